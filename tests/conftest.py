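"""Shared fixtures: scaled-down studies reused across test modules.

The multi-seed nine-region study runs once per session at reduced
resolution (50x50 pixels, 0.4 mm — same 20 mm geometry) and iteration
count, so the method-comparison tests don't each pay for their own
inversions.
"""

import numpy as np
import pytest

import qpamark as q

STUDY_SEEDS = (101, 202, 303, 404, 505)
STUDY_MAX_ITER = 150


@pytest.fixture(scope="session")
def small_nine_region():
    grid = q.GridSpec(50, 50, 0.4)
    optics, labels, marker = q.make_nine_region_phantom(grid)
    sources = q.default_sources(grid, 10)
    return grid, optics, labels, marker, sources


@pytest.fixture(scope="session")
def nine_region_study(small_nine_region):
    """Five methods x five seeds on the reduced nine-region phantom at 30 dB.

    Returns {seed: {method: (InversionResult, psnr_db, region_table)}} with
    methods keyed SIM, SIM_M, GBM, GBM_M, CGBM.
    """
    grid, optics, labels, marker, sources = small_nine_region
    cfg = q.InversionConfig(max_iter=STUDY_MAX_ITER)
    study = {}
    for seed in STUDY_SEEDS:
        _, _, h_m = q.simulate_measurement(optics, sources, snr_db=30.0, seed=seed)
        runs = {
            "SIM": q.run_sim(h_m, 2.0, cfg, sources=sources),
            "SIM_M": q.run_sim(h_m, 2.0, cfg, marker=marker, sources=sources),
            "GBM": q.run_gbm(h_m, 2.0, cfg, sources=sources),
            "GBM_M": q.run_gbm(h_m, 2.0, cfg, marker=marker, sources=sources),
            "CGBM": q.run_gbm_constrained(h_m, 2.0, cfg, marker=marker,
                                          sources=sources),
        }
        study[seed] = {
            name: (res,
                   q.psnr(res.mu_a_hat, optics.mu_a, exclude_mask=marker.mask),
                   q.region_means(res.mu_a_hat, labels).table.set_index("label"))
            for name, res in runs.items()
        }
    return study


@pytest.fixture(scope="session")
def spectral_report():
    """Noise-free multispectral recovery on a reduced grid (GBM + marker)."""
    from qpamark.metrics import recover_spectrum

    grid = q.GridSpec(60, 60, 1.0 / 3.0)
    sources = q.default_sources(grid, 10)
    dataset = []
    for w in range(1, q.phantoms.N_WAVELENGTHS + 1):
        optics, labels, marker = q.make_spectral_phantom(w, grid)
        _, _, h_m = q.simulate_measurement(optics, sources, snr_db=np.inf, seed=0)
        dataset.append((h_m, marker, 2.0, labels))
    return recover_spectrum(dataset, "GBM", q.InversionConfig(max_iter=150),
                            sources=sources)
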