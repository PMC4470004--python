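"""Expression handling: TMM normalization and model initialization.

Raw sequencing counts are depth-normalized with the trimmed mean of M-values
(TMM) method: for each library a scale factor is the precision-weighted mean
of per-feature log2 expression ratios (M) against a reference library, after
double trimming — the most extreme 30 % of M values and 5 % of absolute
intensities (A) on each side are discarded. Factors are rescaled so their
geometric mean is 1; normalized values are counts per million of the
effective (factor-adjusted) library size.

Initialization writes a single individual's expression onto a model: every
concentration is reset to zero, then gene species receive the value keyed by
their Ensembl id in the gene profile, and miRNA-gene species the value keyed
by their miRNA id in the miRNA profile. Expression values are used directly
as token concentrations. Id matching is exact after lower-casing, with the
``hsa-`` prefix stripped from miRNA ids.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mirao import normalize_mirna_id
from .model import MolecularModel, SpeciesKind

logger = logging.getLogger(__name__)

__all__ = ["ExpressionProfile", "load_profile", "tmm_normalize", "initialize_model"]


@dataclass
class ExpressionProfile:
    """One sample's feature-id → expression-value map."""

    values: dict[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if v < 0]
        if bad:
            raise ValueError(f"negative expression for {bad[:3]}")

    def get(self, feature_id: str, default: float | None = None):
        return self.values.get(feature_id, default)

    def __len__(self) -> int:
        return len(self.values)


def load_profile(tsv_source, label: str = "") -> ExpressionProfile:
    """Load a two-column profile (TSV columns feature_id, value)."""
    df = pd.read_csv(tsv_source, sep="\t", dtype={"feature_id": str})
    missing = {"feature_id", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"profile missing columns: {sorted(missing)}")
    if df["feature_id"].duplicated().any():
        raise ValueError("duplicate feature ids in profile")
    return ExpressionProfile(
        values={str(k): float(v) for k, v in zip(df["feature_id"], df["value"])},
        label=label,
    )


def _pick_reference(frac: pd.DataFrame) -> str:
    """Sample whose upper-quartile count fraction is closest to the mean."""
    uq = frac.quantile(0.75, axis=0)
    return (uq - uq.mean()).abs().idxmin()


def tmm_normalize(
    count_matrix: pd.DataFrame,
    reference_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> tuple[pd.Series, pd.DataFrame]:
    """TMM scale factors and the normalized (CPM-of-effective-size) matrix.

    ``count_matrix``: features × samples, raw non-negative counts. Returns
    ``(factors, normalized)``. Reported factors are rescaled to geometric
    mean 1 (the conventional presentation); the normalized matrix is
    ``counts / (libsize * pairwise_factor) * 1e6`` with each sample's
    *pairwise-to-reference* factor, so one sample's normalized values never
    depend on an unrelated library's depth.
    """
    counts = count_matrix.astype(float)
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        zero = list(lib.index[lib == 0])
        raise ValueError(f"sample(s) with zero total count: {zero}")
    if counts.shape[1] == 1:
        _warnings.warn("single sample: TMM factor fixed at 1", stacklevel=2)
        factors = pd.Series([1.0], index=counts.columns)
        return factors, counts / lib * 1e6

    frac = counts / lib
    ref = reference_sample if reference_sample is not None else _pick_reference(frac)
    if ref not in counts.columns:
        raise ValueError(f"reference sample {ref!r} not in matrix")

    raw = {}
    yr = counts[ref].values
    nr = lib[ref]
    for sample in counts.columns:
        yk = counts[sample].values
        nk = lib[sample]
        keep = (yk > 0) & (yr > 0)
        if sample == ref or not keep.any():
            raw[sample] = 1.0
            continue
        fk, fr = yk[keep] / nk, yr[keep] / nr
        m = np.log2(fk / fr)
        a = 0.5 * np.log2(fk * fr)
        # delta-method precision weights of M
        w = (nk - yk[keep]) / (nk * yk[keep]) + (nr - yr[keep]) / (nr * yr[keep])
        n = m.size
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rm = pd.Series(m).rank().values
        ra = pd.Series(a).rank().values
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not sel.any() or w[sel].sum() == 0:
            raw[sample] = 1.0
            continue
        raw[sample] = float(2 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])))

    pairwise = pd.Series(raw, index=counts.columns, dtype=float)
    normalized = counts / (lib * pairwise) * 1e6
    factors = pairwise / np.exp(np.mean(np.log(pairwise)))
    return factors, normalized


def initialize_model(
    model: MolecularModel,
    gene_profile: ExpressionProfile,
    mirna_profile: ExpressionProfile,
) -> MolecularModel:
    """Return a copy of ``model`` initialized with one individual's expression.

    A total reset: every concentration becomes 0, then gene species matched
    in the gene profile (by Ensembl id) and miRNA-gene species matched in
    the miRNA profile (by miRNA id) receive their expression value. Profile
    ids absent from the model and model genes absent from the profiles are
    counted and logged, never fatal.
    """
    init = model.copy()
    genes = {k.lower(): float(v) for k, v in gene_profile.values.items()}
    mirs = {normalize_mirna_id(k): float(v) for k, v in mirna_profile.values.items()}

    matched_gene_keys: set[str] = set()
    matched_mir_keys: set[str] = set()
    unmatched_model_genes = 0
    for sp in init.species.values():
        sp.concentration = 0.0
        if sp.kind is not SpeciesKind.GENE:
            continue
        if sp.id.startswith("miRgene:"):
            key = normalize_mirna_id(sp.id[len("miRgene:"):])
            if key in mirs:
                sp.concentration = mirs[key]
                matched_mir_keys.add(key)
            else:
                unmatched_model_genes += 1
        else:
            key = sp.id.lower()
            if key in genes:
                sp.concentration = genes[key]
                matched_gene_keys.add(key)
            elif normalize_mirna_id(sp.id) in mirs:
                # miRNA gene not created by the extension, matched by its own id
                mkey = normalize_mirna_id(sp.id)
                sp.concentration = mirs[mkey]
                matched_mir_keys.add(mkey)
            else:
                unmatched_model_genes += 1

    unmatched_profile = (len(genes) - len(matched_gene_keys)) + (
        len(mirs) - len(matched_mir_keys)
    )
    if unmatched_profile:
        logger.info("%d profile id(s) not present in the model", unmatched_profile)
    if unmatched_model_genes:
        logger.info("%d model gene(s) not covered by the profiles (stay 0)", unmatched_model_genes)
    return init
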