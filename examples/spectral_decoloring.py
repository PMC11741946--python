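"""Spectral decoloring with the fluence marker.

The two-concentric-disc phantom has a spectrally flat marker (0.2 mm^-1)
inside an "unknown chromophore" annulus whose absorption peaks at the
middle wavelength, embedded in a background whose absorption rises with
wavelength — so the apparent (absorbed-energy) spectrum of the annulus is
colored by the background. GBM with the marker recovers the true spectrum;
the equal-fluence shortcut recovers the shape but not the magnitude.
"""

import numpy as np

import qpamark as q
from qpamark.metrics import recover_spectrum
from qpamark.phantoms import UNKNOWN_SPECTRUM

grid = q.GridSpec(60, 60, 1.0 / 3.0)
sources = q.default_sources(grid, 10)
dataset = []
for w in range(1, 6):
    optics, labels, marker = q.make_spectral_phantom(w, grid)
    _, _, h_m = q.simulate_measurement(optics, sources, snr_db=np.inf, seed=0)
    dataset.append((h_m, marker, 2.0, labels))

report = recover_spectrum(dataset, "GBM", q.InversionConfig(max_iter=150),
                          sources=sources)

print("unknown-chromophore spectrum (annulus region, mu_a in mm^-1):")
print(f"{'wavelength':>10} {'truth':>8} {'marker method':>14} {'equal fluence':>14}")
sub = report.table[report.table["label"] == 4].sort_values("wavelength")
for _, row in sub.iterrows():
    print(f"{int(row['wavelength']):>10} {row['truth']:8.3f} "
          f"{row['recovered']:14.4f} {row['equal_fluence']:14.4f}")

stats = report.error_stats.set_index(["method", "label"])
print("\nmean +- SD of |mu_a error| across wavelengths (annulus):")
for method in ("recovered", "equal_fluence"):
    m = stats.loc[(method, 4), "mean_abs_error"]
    s = stats.loc[(method, 4), "sd_abs_error"]
    print(f"  {method:>14}: {m:.4f} +- {s:.4f} mm^-1")

print("\nThe marker method restores both the unimodal shape (peak at")
print(f"wavelength 3, truth {UNKNOWN_SPECTRUM[2]} mm^-1) and the magnitude;")
print("equal fluence overestimates because the marker's interior fluence is")
print("much lower than the annulus fluence.")
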