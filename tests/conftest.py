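"""Shared fixtures: published benchmark numbers and small synthetic inputs."""

import numpy as np
import pandas as pd
import pytest

from onoffcalls import MixtureParams, ProbeLevelDataset

# Fitted parameter vectors reported for the U95 Latin-square spike-in arrays
# (pooled over all probe sets and arrays) and for the neuroblastoma cohort's
# favorable / unfavorable outcome groups (theta = (mu, alpha, xi, sigma2)).
U95_THETA = (1.00, 1.00, 0.35, 0.15)
NB_FAVORABLE_THETA = (1.96, 1.10, 0.17, 0.13)
NB_UNFAVORABLE_THETA = (1.86, 1.16, 0.16, 0.14)


@pytest.fixture(scope="session")
def u95_params() -> MixtureParams:
    return MixtureParams(*U95_THETA)


@pytest.fixture(scope="session")
def nb_favorable_params() -> MixtureParams:
    return MixtureParams(*NB_FAVORABLE_THETA)


@pytest.fixture(scope="session")
def spikein_counts() -> pd.DataFrame:
    """Published per-concentration call counts on the U95 spike-in arrays.

    Columns pair the detection (P/M/A) calls with the On/Off calls at the
    X >= 11 cutoff; rows are true spike-in concentrations in pM.
    """
    rows = [
        # conc, P, M, A, On, Off, total
        (0, 1, 0, 58, 4, 55, 59),
        (0.25, 10, 0, 49, 27, 32, 59),
        (0.5, 21, 4, 33, 44, 14, 58),
        (1.0, 22, 1, 36, 48, 11, 59),
        (2, 37, 3, 19, 52, 7, 59),
        (4, 48, 2, 9, 56, 3, 59),
        (8, 58, 1, 0, 59, 0, 59),
        (16, 59, 0, 0, 59, 0, 59),
        (32, 59, 0, 0, 59, 0, 59),
        (64, 50, 0, 0, 50, 0, 50),
        (128, 50, 0, 0, 50, 0, 50),
        (256, 59, 0, 0, 59, 0, 59),
        (512, 68, 0, 0, 68, 0, 68),
        (1024, 69, 0, 0, 69, 0, 69),
    ]
    df = pd.DataFrame(rows, columns=["concentration_pM", "mas5_detected",
                                     "mas5_marginal", "mas5_undetected",
                                     "onoff_detected", "onoff_undetected",
                                     "total"])
    df = df.set_index("concentration_pM")
    df["mas5_total"] = df["total"]
    df["onoff_total"] = df["total"]
    return df.drop(columns="total")


@pytest.fixture(scope="session")
def top5_pr_on() -> pd.DataFrame:
    """Published top-five candidate genes with group probabilities of 'On'."""
    return pd.DataFrame({
        "gene": ["SLC30A3", "MYCN*", "MYCNOS", "NPW", "MYCN"],
        "pr_on_fav": [0.26, 0.38, 0.38, 0.16, 0.19],
        "pr_on_unfav": [0.89, 0.94, 0.88, 0.58, 0.58],
    })


def make_probe_table(n_genes: int = 5, n_samples: int = 3, j: int = 4,
                     seed: int = 0) -> pd.DataFrame:
    """A small random but valid long-format probe table."""
    rng = np.random.default_rng(seed)
    recs = []
    for g in range(n_genes):
        for p in range(1, j + 1):
            for s in range(n_samples):
                recs.append((f"PS{g}", p, f"S{s}",
                             float(rng.gamma(2.0, 50.0)),
                             float(rng.gamma(2.0, 50.0))))
    return pd.DataFrame(recs, columns=["probeset_id", "probe_pair_index",
                                       "sample_id", "pm", "mm"])


@pytest.fixture()
def small_dataset() -> ProbeLevelDataset:
    return ProbeLevelDataset.from_table(make_probe_table())
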