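"""Quantify birefringence color composition of a phantom.

Hue-band percentages (red, yellow, green, blue on the 0-180 OpenCV-style hue
scale) are computed over the whole RGB birefringence rendering; the fibrosis
invasion fraction (FiF) is their sum expressed as a fraction. Red and yellow
pixels mark strongly birefringent (collagen-rich) tissue, so both rise with
severity.
"""
from octfib import class_presets, color_percentages, default_bands, generate_phantom

for band in default_bands():
    print(f"band {band.name}: hue [{band.hue_lo}, {band.hue_hi})")

print()
for label, spec in class_presets().items():
    pair, _truth = generate_phantom(spec)
    comp = color_percentages(pair.birefringence)
    pcts = ", ".join(f"{name}={pct:.2f}%" for name, pct in comp.percent.items())
    print(f"{label:>8}: {pcts}, FiF={comp.fif:.4f}")
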