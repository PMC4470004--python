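"""Drug specifications and their mapping onto model reactions.

A drug is a set of (target, iKd) pairs: the target is a protein or complex
the drug binds, iKd its experimentally measured dissociation constant in nM.
Treatment is modeled by annotating every reaction *catalyzed* by a target
(target appears in the enzyme list) with an inhibitor entry carrying the
drug's iKd and the administered concentration; the simulation engine then
multiplies the reaction speed by iKd / [I].

The built-in catalogue packages twelve agents: ten kinase inhibitors with
dissociation constants from kinome-wide binding assays, plus sirolimus
(mTor complex II, 0.65 nM) and LY294002 (PI3K, 210 nM).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import pandas as pd

from .model import Inhibitor, MolecularModel

logger = logging.getLogger(__name__)

__all__ = ["DrugTarget", "DrugSpec", "builtin_drugs", "load_drugs", "apply_treatment"]


@dataclass(frozen=True)
class DrugTarget:
    """One binding target: species name/id and dissociation constant in nM."""

    name: str
    ikd: float

    def __post_init__(self) -> None:
        if self.ikd <= 0:
            raise ValueError(f"target {self.name!r}: iKd must be > 0")


@dataclass(frozen=True)
class DrugSpec:
    name: str
    targets: tuple[DrugTarget, ...]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"drug {self.name!r}: needs at least one target")

    @property
    def ikd(self) -> float:
        """iKd of a single-target drug; ambiguous (error) otherwise."""
        if len(self.targets) != 1:
            raise ValueError(f"drug {self.name!r} has {len(self.targets)} targets")
        return self.targets[0].ikd


def _drug(name: str, *targets: tuple[str, float]) -> DrugSpec:
    return DrugSpec(name, tuple(DrugTarget(t, kd) for t, kd in targets))


_CATALOGUE: tuple[DrugSpec, ...] = (
    _drug(
        "dasatinib",
        ("ABL1", 0.53),
        ("EPHA3", 0.09),
        ("EPHA5/8", 0.24),
        ("PDGFRA", 0.47),
        ("LYN", 0.57),
        ("KIT", 0.62),
        ("SRC", 0.21),
    ),
    _drug("erlotinib", ("EGFR", 0.67), ("ERBB4", 230.0), ("LYN", 530.0), ("SRC", 700.0)),
    _drug("everolimus", ("MTOR", 2.2)),
    _drug("gefitinib", ("EGFR", 1.0), ("ERBB2", 3500.0), ("ERBB4", 410.0), ("LYN", 990.0)),
    _drug(
        "imatinib",
        ("ABL1", 12.0),
        ("ABL2", 10.0),
        ("KIT", 14.0),
        ("PDGFRA", 31.0),
        ("PDGFRB", 14.0),
    ),
    _drug("lapatinib", ("EGFR", 2.4), ("ERBB2", 7.0), ("ERBB4", 54.0)),
    _drug("nilotinib", ("KIT", 22.0), ("PDGFRB", 22.0)),
    _drug("sorafenib", ("DDR1", 1.5), ("DDR2", 6.6)),
    _drug("sunitinib", ("FLT3", 0.47), ("KIT", 0.37), ("PDGFRA", 0.79), ("PDGFRB", 0.08)),
    _drug("temsirolimus", ("MTOR", 2.2), ("VEGFR", 0.75)),
    # specific mTor-complex-II inhibitor
    _drug("sirolimus", ("mTor complex II", 0.65)),
    # PI3K inhibitor (PIP2 -> PIP3 conversion)
    _drug("LY294002", ("PI3K", 210.0)),
)


def builtin_drugs() -> dict[str, DrugSpec]:
    """The packaged drug catalogue, keyed by lower-cased drug name."""
    return {d.name.lower(): d for d in _CATALOGUE}


def load_drugs(source) -> dict[str, DrugSpec]:
    """Load user drug specs from TSV (columns name, target, ikd_nm) or JSON.

    JSON shape: ``{"drugname": [["TARGET", ikd_nm], ...], ...}``.
    """
    if str(source).endswith(".json"):
        with open(source) as fh:
            raw = json.load(fh)
        return {
            name.lower(): _drug(name, *[(t, float(kd)) for t, kd in targets])
            for name, targets in raw.items()
        }
    df = pd.read_csv(source, sep="\t")
    missing = {"name", "target", "ikd_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"drug table missing columns: {sorted(missing)}")
    out: dict[str, DrugSpec] = {}
    for name, grp in df.groupby("name", sort=True):
        out[str(name).lower()] = _drug(
            str(name), *[(str(r.target), float(r.ikd_nm)) for r in grp.itertuples()]
        )
    return out


def _norm(name: str) -> str:
    """Enzyme-identity normalization: case-insensitive, phospho prefix stripped."""
    n = name.casefold().strip()
    if n.startswith("p-"):
        n = n[2:]
    return n


def apply_treatment(
    model: MolecularModel, drug: DrugSpec, inhibitor_conc: float = 1.0
) -> MolecularModel:
    """Return a copy of ``model`` with the drug's inhibition annotated.

    Every reaction whose enzyme list contains a drug target (matched on
    species id or display name, case-insensitively, ignoring a phospho
    "P-" prefix) gains an inhibitor entry (drug name, target's iKd,
    [I] = ``inhibitor_conc``). A reaction catalyzed by several targets gets
    one entry per matched target — the inhibition factors multiply. Species,
    kinetic parameters and topology are never changed. If nothing matches, a
    warning is logged and an unmodified copy returned (FCA then yields
    P = 1).
    """
    if inhibitor_conc < 0:
        raise ValueError("inhibitor_conc must be >= 0")
    by_target = {_norm(t.name): t for t in drug.targets}
    treated = model.copy()
    n_hit = 0
    for rx in treated.reactions:
        for eid in rx.enzymes:
            sp = treated.species[eid]
            tgt = by_target.get(_norm(sp.id)) or by_target.get(_norm(sp.name))
            if tgt is not None:
                rx.inhibitors.append(Inhibitor(ref=drug.name, ikd=tgt.ikd, conc=inhibitor_conc))
                n_hit += 1
    if n_hit == 0:
        logger.warning("drug %r matched no reaction in the model", drug.name)
    return treated
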