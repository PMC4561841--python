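"""Published reference tables from the boreal chorus frog wetland study.

These small tables reproduce summary numbers reported by the Colorado
montane-wetland landscape-genetics study this pipeline is built around:
per-wetland sample bookkeeping, the gravity-model selection ranking, and
the per-wetland connectivity decompositions for the three network
constructions. They are bundled for validation and worked examples — the
underlying genotypes and wetland coordinates were never published, so
full-pipeline comparisons use the synthetic generator instead.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "sample_sizes",
    "gravity_selection",
    "wetland_connectivity",
]


def sample_sizes() -> pd.DataFrame:
    """Per-wetland sample bookkeeping: adults, tadpoles, tadpoles retained
    after sibship screening, and the final genotyped sample size."""
    rows = [
        (1, "Laramie Lake North", 9, 0, 0, 9),
        (2, "Spruce bog", 3, 30, 24, 27),
        (3, "Laramie Lake South", 11, 0, 0, 11),
        (4, "Spencer 7", 2, 0, 0, 2),
        (5, "Old Highway 14", 8, 19, 14, 22),
        (6, "Sylvatica", 29, 40, 31, 60),
        (7, "Spencer 16", 5, 0, 0, 5),
        (8, "Spencer 12", 2, 30, 14, 16),
        (9, "Spencer 11", 0, 30, 27, 27),
        (10, "Lily", 19, 0, 0, 19),
        (11, "Mosquitos", 11, 0, 0, 11),
        (12, "Matthews", 13, 0, 0, 13),
        (13, "Zimmerman 1", 0, 31, 28, 28),
        (14, "Zimmerman 6", 0, 27, 27, 27),
        (15, "Zimmerman 5", 0, 5, 5, 5),
        (16, "Tunnel B", 0, 30, 14, 14),
        (17, "Lily Pond Lake", 2, 32, 22, 24),
        (18, "Mosquito 2", 2, 0, 0, 2),
    ]
    return pd.DataFrame(
        rows,
        columns=["site_id", "name", "adults", "tadpoles", "screened_tadpoles", "final_n"],
    )


def gravity_selection() -> pd.DataFrame:
    """Published gravity-model ranking: predictor set, printed parameter
    count, ΔAIC, and maximum log-likelihood."""
    rows = [
        ("distance, srr_bet, pratio_at, PC_steppingstone_at", 4, 0.00, -6.04),
        ("distance, srr_bet, pratio_at, pratio_bet, PC_steppingstone_at", 5, 0.70, -5.39),
        ("distance, srr_bet, pratio_at, cti_at, PC_steppingstone_at", 5, 0.92, -5.51),
        ("distance, srr_bet, pratio_bet, pratio_at, cti_at, PC_steppingstone_at", 6, 1.62, -4.85),
        ("distance, pratio_bet, pratio_at, PC_steppingstone_at", 4, 1.70, -6.89),
        ("srr_bet", 1, 1.81, -9.47),
        ("pratio_at", 1, 1.92, -8.20),
        ("distance", 1, 2.73, -9.47),
        ("pratio_bet", 1, 2.96, -8.59),
        ("cti_at", 1, 3.70, -6.96),
        ("PC_steppingstone_at", 1, 9.33, -11.77),
    ]
    return pd.DataFrame(rows, columns=["variables", "n_params", "delta_aic", "loglik"])


def wetland_connectivity() -> pd.DataFrame:
    """Published per-wetland connectivity decomposition (percent) for the
    spatial-breeding, temporal-breeding, and stepping-stone networks."""
    rows = [
        # id, snow, area, PC (sp, tmp, step), Intra (...), Flux (...), Connector (...)
        ("A", "neutral", 400, 10.3, 0.05, 2.09e0, 0.8, 0.03, 1.93e0, 9.5, 0.02, 1.58e-1, 0.0, 0.0, 0.0),
        ("B", "neutral", 3000, 11.5, 2.1, 2.18e0, 0.8, 1.51, 1.93e0, 10.68, 0.59, 2.49e-1, 2.18e-2, 0.0, 4.236e-4),
        ("C", "neutral", 20000, 2.15, 68.47, 1.05e-1, 0.03, 67.14, 6.79e-2, 2.11, 1.32, 3.73e-2, 1.72e-2, 0.0, 2.36e-5),
        ("D", "neutral", 10000, 8.28, 16.79, 1.74e1, 7.19, 16.79, 1.74e1, 1.09, 0.0, 0.0, 0.0, 0.0, 0.0),
        ("E", "low", 1800, 7.36, 0.16, 1.14e0, 0.45, 0.16, 1.09e0, 6.91, 0.0, 5.28e-2, 1.53e-3, 0.0, 0.0),
        ("F", "low", 4000, 26.52, 0.96, 1.29e1, 4.99, 0.8, 1.21e1, 21.52, 0.16, 8.13e-1, 4.45e-3, 6.69e-5, 3.16e-5),
        ("G", "low", 2000, 5.51, 0.35, 1.14e0, 0.16, 0.2, 3.91e-1, 5.28, 0.15, 7.48e-1, 6.93e-2, 0.0, 0.0),
        ("H", "high", 8750, 1.2, 2.75, 4.70e-1, 0.01, 2.66, 1.93e-2, 1.19, 0.1, 4.51e-1, 0.0, 0.0, 0.0),
        ("I", "high", 675, 45.24, 0.11, 4.88e1, 19.97, 0.02, 4.83e1, 25.25, 0.1, 5.02e-1, 1.66e-2, 0.0, 0.0),
        ("J", "high", 4000, 4.49, 0.58, 5.09e-1, 0.2, 0.55, 4.83e-1, 4.29, 0.03, 2.62e-2, 0.0, 0.0, 0.0),
        ("K", "high", 1350, 21.07, 0.12, 9.40e0, 3.82, 0.06, 9.25e0, 17.23, 0.05, 1.56e-1, 1.22e-2, 0.0, 0.0),
        ("L", "high", 750, 1.98, 0.11, 1.72e-1, 0.02, 0.02, 5.50e-2, 1.94, 0.09, 1.17e-1, 2.00e-2, 2.09e-4, 3.55e-4),
        ("M", "high", 6300, 4.13, 3.34, 3.14e-1, 0.09, 1.38, 2.20e-1, 4.02, 1.96, 9.38e-2, 1.37e-2, 0.0, 1.19e-5),
        ("N", "high", 700, 5.84, 0.02, 4.79e0, 1.98, 0.02, 4.79e0, 3.86, 0.0, 3.20e-6, 0.0, 0.0, 0.0),
        ("O", "high", 1000, 1.0, 0.05, 1.03e-1, 0.02, 0.03, 5.92e-2, 0.97, 0.02, 4.39e-2, 3.25e-3, 0.0, 0.0),
        ("P", "high", 200, 1.34, 0.0, 1.54e-1, 0.05, 0.0, 1.21e-1, 1.29, 0.0, 3.32e-2, 0.0, 0.0, 0.0),
        ("Q", "high", 12000, 0.29, 0.02, 3.03e-2, 0.0, 0.01, 4.83e-3, 0.29, 0.02, 2.54e-2, 2.96e-3, 1.85e-4, 0.0),
        ("R", "high", 450, 1.4, 7.67, 9.40e-2, 0.01, 4.99, 2.45e-2, 1.37, 2.67, 6.94e-2, 2.29e-2, 0.0, 1.50e-4),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "wetland",
            "snowpack",
            "area_m2",
            "pc_spatial",
            "pc_temporal",
            "pc_step",
            "intra_spatial",
            "intra_temporal",
            "intra_step",
            "flux_spatial",
            "flux_temporal",
            "flux_step",
            "connector_spatial",
            "connector_temporal",
            "connector_step",
        ],
    )
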