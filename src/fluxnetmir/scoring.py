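"""Sensitivity scores, responder calls, correlations and ROC/AUC.

The model-based sensitivity score of a simulated individual is
``log10(P) + K`` with the hallmark fold change P (treatment / control) and
the calibration constant K = 5.2; base 10 makes the score commensurate with
the experimental GI50 scale (-log10 mol/L of drug giving 50 % growth
inhibition). P < 1 — equivalently score < K — classifies an individual as a
responder.

Correlations between model-based and experimental scores are computed per
treatment (Pearson) and pooled over treatments with the Bland–Altman
within-subject correlation: both variables are centered on their treatment
means before pooling, which removes per-treatment offsets and correlates
only the within-treatment co-variation. The difference between two
aggregate correlations (e.g. scores computed with vs. without miRNA input)
is tested by a seeded bootstrap over samples. Group discrimination
(e.g. responder-associated phenotypes) is quantified by the rank
(Mann–Whitney) AUC, ties counting 1/2.
"""

from __future__ import annotations

import logging
import math
import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_K",
    "SensitivityRecord",
    "sensitivity_score",
    "classify_responder",
    "pearson_by_treatment",
    "aggregate_correlation",
    "correlation_difference_test",
    "roc_auc",
]

#: calibration constant K of the model-based sensitivity score
DEFAULT_K = 5.2


def sensitivity_score(P: float, K: float = DEFAULT_K) -> float:
    """Model-based sensitivity score, ``log10(P) + K``. Requires P > 0."""
    if P <= 0:
        raise ValueError(f"P must be > 0, got {P}")
    return math.log10(P) + K


def classify_responder(P: float) -> str:
    """'responder' when the hallmark fold change P < 1, else 'non-responder'.

    The boundary P == 1 (treatment changes nothing) is classified
    non-responder.
    """
    if P <= 0:
        raise ValueError(f"P must be > 0, got {P}")
    return "responder" if P < 1 else "non-responder"


@dataclass
class SensitivityRecord:
    """One (sample, treatment) scored pair.

    ``model_score`` is derived from P on construction when omitted;
    ``gi50`` is the experimental score when available.
    """

    sample_id: str
    treatment: str
    P: float
    model_score: float | None = None
    gi50: float | None = None

    def __post_init__(self) -> None:
        if self.model_score is None:
            self.model_score = sensitivity_score(self.P)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in records],
                "treatment": [r.treatment for r in records],
                "model_score": [r.model_score for r in records],
                "gi50": [r.gi50 for r in records],
            }
        )
    return df.dropna(subset=["model_score", "gi50"])


def pearson_by_treatment(records) -> dict[str, tuple[float, float]]:
    """Per-treatment Pearson r (model vs. experimental score) with two-sided p.

    Treatments with fewer than 3 complete pairs are skipped with a warning;
    zero-variance treatments yield (nan, nan) and a warning.
    """
    df = _as_frame(records)
    out: dict[str, tuple[float, float]] = {}
    for treatment, grp in df.groupby("treatment", sort=True):
        if len(grp) < 3:
            _warnings.warn(f"treatment {treatment!r}: <3 pairs, skipped", stacklevel=2)
            continue
        x = grp["model_score"].to_numpy(float)
        y = grp["gi50"].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            _warnings.warn(f"treatment {treatment!r}: zero variance", stacklevel=2)
            out[treatment] = (float("nan"), float("nan"))
            continue
        r, p = stats.pearsonr(x, y)
        out[treatment] = (float(r), float(p))
    return out


def aggregate_correlation(records, min_pairs: int = 3) -> float:
    """Pooled within-treatment (Bland–Altman) correlation.

    Both scores are centered on their per-treatment means, pooled across
    treatments and correlated. Adding any per-treatment constant offset to
    either score leaves the result unchanged. Requires at least two
    treatments with ``min_pairs`` complete pairs each.
    """
    df = _as_frame(records)
    sizes = df.groupby("treatment")["model_score"].size()
    keep = sizes.index[sizes >= min_pairs]
    if len(keep) < 2:
        raise ValueError(
            f"need >=2 treatments with >={min_pairs} pairs, have {len(keep)}"
        )
    df = df[df["treatment"].isin(keep)]
    cx = df["model_score"] - df.groupby("treatment")["model_score"].transform("mean")
    cy = df["gi50"] - df.groupby("treatment")["gi50"].transform("mean")
    if np.ptp(cx.values) == 0 or np.ptp(cy.values) == 0:
        raise ValueError("degenerate pooled variance; aggregate correlation undefined")
    r, _ = stats.pearsonr(cx.to_numpy(float), cy.to_numpy(float))
    return float(r)


def correlation_difference_test(
    records_a,
    records_b,
    n_boot: int = 2000,
    seed: int = 0,
    min_pairs: int = 3,
) -> float:
    """Bootstrap two-sided p for equality of two aggregate correlations.

    ``records_a`` and ``records_b`` score the same samples/treatments two
    different ways. Samples (cell lines/patients) are resampled with
    replacement; both aggregate correlations are recomputed on each
    resample and the two-sided p-value for Δr = 0 is read off the bootstrap
    distribution. Deterministic for a fixed seed.
    """
    if n_boot < 100:
        _warnings.warn("n_boot < 100: p-value will be unstable", stacklevel=2)
    da, db = _as_frame(records_a), _as_frame(records_b)
    samples = sorted(set(da["sample_id"]) | set(db["sample_id"]))
    rng = np.random.default_rng(seed)
    deltas = []
    while len(deltas) < n_boot:
        chosen = rng.choice(samples, size=len(samples), replace=True)
        counts = pd.Series(chosen).value_counts()

        def resample(df):
            parts = [df[df["sample_id"] == s] for s, c in counts.items() for _ in range(c)]
            return pd.concat(parts, ignore_index=True)

        try:
            ra = aggregate_correlation(resample(da), min_pairs=min_pairs)
            rb = aggregate_correlation(resample(db), min_pairs=min_pairs)
        except ValueError:
            continue  # degenerate resample
        deltas.append(ra - rb)
    deltas = np.asarray(deltas)
    p_lo = float(np.mean(deltas <= 0))
    p_hi = float(np.mean(deltas >= 0))
    return min(1.0, 2.0 * min(p_lo, p_hi))


def roc_auc(scores, binary_labels) -> float:
    """Mann–Whitney AUC of ``scores`` discriminating the positive class.

    ``binary_labels`` are truthy for positives; ties contribute 1/2. Raises
    when only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([bool(v) for v in binary_labels])
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)
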