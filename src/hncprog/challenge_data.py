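"""Published RADCURE-challenge leaderboard used as reference data.

The 12 crowd-sourced submissions to the RADCURE head-and-neck prognostic
modeling challenge, with their test-set AUROC, average precision and
C-index point estimates (as publicly reported, three decimals).  Bundled
so that metric-agreement analyses can be reproduced without access to the
underlying cohort; note that correlations recomputed from these rounded
values can differ from unrounded originals by up to ~0.005.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["radcure_challenge_table"]

_ROWS = [
    (1, "Deep MTLR, EMR features + tumor volume", "combined",
     0.823, 0.505, 0.801),
    (2, "Fuzzy logistic regression / Cox PH, EMR + tumor volume", "combined",
     0.816, 0.502, 0.746),
    (3, "Fuzzy logistic regression / Cox PH, EMR + engineered radiomics",
     "combined", 0.808, 0.490, 0.748),
    (4, "MTLR, EMR features only", "emr", 0.798, 0.429, 0.785),
    (5, "3D convnet on tumor patch + EMR features", "combined",
     0.786, 0.420, 0.774),
    (6, "2D convnet on largest GTV slice + EMR features", "combined",
     0.783, 0.438, 0.773),
    (7, "3D DenseNet on tumor patch + EMR features, multitask head",
     "combined", 0.780, 0.353, 0.781),
    (8, "MLP with SELU activation, EMR features only", "emr",
     0.779, 0.415, 0.768),
    (9, "Two-stream 3D DenseNet, multitask head, imaging only", "radiomics",
     0.766, 0.311, 0.748),
    (10, "2D convnet on largest GTV slice, imaging only", "radiomics",
     0.735, 0.357, 0.722),
    (11, "3D convnet on tumor patch, imaging only", "radiomics",
     0.717, 0.268, 0.706),
    (12, "Fuzzy logistic regression / Cox PH, engineered radiomics only",
     "radiomics", 0.716, 0.341, 0.695),
]


def radcure_challenge_table() -> pd.DataFrame:
    """The 12-submission leaderboard: rank, description, input category and
    the three reported performance metrics."""
    return pd.DataFrame(
        _ROWS, columns=["rank", "description", "category",
                        "auroc", "ap", "c_index"])
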