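"""The miR-add-on: splice validated miRNA regulation into a molecular model.

Two curated tables drive the extension:

* **miRT** — validated miRNA → target gene records, keyed by the target's
  Ensembl gene id, each entry carrying the miRNA id and a PubMed reference.
* **TFmiR** — transcription-factor → miRNA records, keyed by miRNA id, each
  entry carrying the TF's Ensembl id, the regulation sign (activation or
  repression) and a PubMed reference.

For every model gene that is a miRT key *and* has an mRNA in the model, the
extension adds, once per new mature miRNA: a miRNA gene (nucleus), a nuclear
miRNA, a transcription reaction (miRNA gene as template; activating TFs as
enzymes, repressive TFs as inhibitors) and a nucleus→cytoplasm translocation
producing the cytoplasmic miRNA. Per (miRNA, target mRNA) pair one
miRNA-binding reaction sequesters cytoplasmic miRNA plus target mRNA into a
silenced miRNA:mRNA complex (RISC simplified to a single binding step), and
one decay reaction degrades that complex — the silenced transcript is
destroyed and the miRNA turned over with it, so silencing is a sustained
drain on the target mRNA pool, never a translated intermediate. All
mature-miRNA species are shared across targets — targets compete for a
common miRNA pool.

Clearance reactions run faster than production (translocation and target
binding at 2k against the default kinetic parameter k; complex decay as a
fast first-order clearance): each pool then settles strictly below its
firing guard instead of oscillating at it, which the steady-state detector
would never accept.

Ids of created objects are deterministic (``miRgene:<mir>``,
``miR:<mir>:nuc``, ``miR:<mir>:cyt``, ``cx:<mir>:<mRNA-id>``), which makes
the extension reproducible byte-for-byte and idempotent.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field

import pandas as pd

from .model import (
    Compartment,
    Inhibitor,
    MolecularModel,
    Reaction,
    ReactionType,
    Species,
    SpeciesKind,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MiRTTable",
    "TFmiRTable",
    "normalize_mirna_id",
    "load_mirt",
    "load_tfmir",
    "extend_model",
]

#: default kinetic parameter for reactions created by the extension; the
#: underlying kinetic values of published models are empirical and unprinted.
DEFAULT_K = 0.01

#: default iKd (token units) for a repressive TF acting as transcription inhibitor
DEFAULT_REPRESSOR_IKD = 1.0

#: first-order clearance rate of silenced miRNA:mRNA complexes; fast, so the
#: complex pool stays far below the binding reaction's firing guard
DEFAULT_COMPLEX_DECAY_K = 0.5

#: enzymatic dissociation constant applied per activating TF on created
#: transcription reactions (token units). Set above typical TF abundance so
#: TF-driven miRNA transcription is sub-saturated: without it, a TF at tens
#: of tokens multiplies the speed past the downstream clearance and the
#: nuclear miRNA pool pins at its firing guard instead of converging.
DEFAULT_TF_EKD = 25.0


def normalize_mirna_id(mid: str) -> str:
    """Canonical miRNA id: lower-case, species prefix ``hsa-`` stripped."""
    m = mid.strip().lower()
    if m.startswith("hsa-"):
        m = m[4:]
    return m


@dataclass
class MiRTTable:
    """Validated miRNA-target records keyed by Ensembl gene id."""

    entries: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def add(self, gene_id: str, mirna_id: str, pubmed: str) -> None:
        if not gene_id:
            raise ValueError("miRT key (Ensembl gene id) must be non-empty")
        if not mirna_id:
            raise ValueError("miRT entry needs a miRNA id")
        self.entries.setdefault(gene_id, []).append((mirna_id, pubmed))

    def __getitem__(self, gene_id: str) -> list[tuple[str, str]]:
        return self.entries[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class TFmiRTable:
    """TF→miRNA transcriptional-regulation records keyed by miRNA id."""

    REGULATIONS = ("activation", "repression")

    entries: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)

    def add(self, mirna_id: str, tf_gene_id: str, regulation: str, pubmed: str) -> None:
        if not mirna_id:
            raise ValueError("TFmiR key (miRNA id) must be non-empty")
        if regulation not in self.REGULATIONS:
            raise ValueError(
                f"regulation must be one of {self.REGULATIONS}, got {regulation!r}"
            )
        self.entries.setdefault(normalize_mirna_id(mirna_id), []).append(
            (tf_gene_id, regulation, pubmed)
        )

    def __getitem__(self, mirna_id: str) -> list[tuple[str, str, str]]:
        return self.entries[normalize_mirna_id(mirna_id)]

    def __contains__(self, mirna_id: str) -> bool:
        return normalize_mirna_id(mirna_id) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def _read_tsv(source, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype=str).fillna("")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"table missing required columns: {sorted(missing)}")
    ndup = int(df.duplicated().sum())
    if ndup:
        _warnings.warn(f"{ndup} duplicate row(s) removed", stacklevel=3)
        df = df.drop_duplicates()
    return df


def load_mirt(tsv_source) -> MiRTTable:
    """Load a miRNA-target table (TSV columns gene_id, mirna_id, pubmed)."""
    df = _read_tsv(tsv_source, ["gene_id", "mirna_id", "pubmed"])
    table = MiRTTable()
    for row in df.itertuples(index=False):
        table.add(row.gene_id, row.mirna_id, row.pubmed)
    return table


def load_tfmir(tsv_source) -> TFmiRTable:
    """Load a TF→miRNA table (TSV columns mirna_id, tf_gene_id, regulation, pubmed)."""
    df = _read_tsv(tsv_source, ["mirna_id", "tf_gene_id", "regulation", "pubmed"])
    table = TFmiRTable()
    for i, row in enumerate(df.itertuples(index=False)):
        if row.regulation not in TFmiRTable.REGULATIONS:
            raise ValueError(
                f"row {i}: regulation must be 'activation' or 'repression', got {row.regulation!r}"
            )
        table.add(row.mirna_id, row.tf_gene_id, row.regulation, row.pubmed)
    return table


def _target_mrnas(model: MolecularModel, gene_id: str) -> list[str]:
    """mRNA products of the gene's transcription reaction(s)."""
    out: list[str] = []
    for rx in model.reactions:
        if rx.rtype is not ReactionType.TRANSCRIPTION:
            continue
        if gene_id in rx.enzymes or gene_id in rx.reactants:
            for pid in rx.products:
                if model.species[pid].kind is SpeciesKind.MRNA and pid not in out:
                    out.append(pid)
    return out


def extend_model(
    model: MolecularModel,
    mirt: MiRTTable,
    tfmir: TFmiRTable,
    k: float = DEFAULT_K,
    repressor_ikd: float = DEFAULT_REPRESSOR_IKD,
    k_complex_decay: float = DEFAULT_COMPLEX_DECAY_K,
    tf_ekd: float = DEFAULT_TF_EKD,
) -> MolecularModel:
    """Add miRNA regulation to a model; returns an extended copy.

    Matching: a model gene participates when its id is a miRT key and the
    model contains the gene's transcript (binding needs a target mRNA);
    genes without a transcript are skipped with a logged warning. TF
    regulation is attached only for TFs whose Ensembl id resolves to a model
    species. Re-running the extension on its own output adds nothing.
    """
    ext = model.copy()

    # matched (mirna, [target mRNA ids]) pairs, in deterministic model order
    mirna_targets: dict[str, list[str]] = {}
    for sp in model.species.values():
        if sp.kind is not SpeciesKind.GENE or sp.id not in mirt:
            continue
        mrnas = _target_mrnas(model, sp.id)
        if not mrnas:
            logger.warning(
                "gene %r matches miRT but has no mRNA in the model; skipped", sp.id
            )
            continue
        for mirna_id, _pubmed in mirt[sp.id]:
            mid = normalize_mirna_id(mirna_id)
            tgt = mirna_targets.setdefault(mid, [])
            for mrna in mrnas:
                if mrna not in tgt:
                    tgt.append(mrna)

    for mid, mrnas in mirna_targets.items():
        gid = f"miRgene:{mid}"
        nuc = f"miR:{mid}:nuc"
        cyt = f"miR:{mid}:cyt"
        if gid not in ext.species:
            ext.add_species(Species(gid, gid, SpeciesKind.GENE, Compartment.NUCLEUS))
            ext.add_species(Species(nuc, nuc, SpeciesKind.MIRNA, Compartment.NUCLEUS))
            ext.add_species(Species(cyt, cyt, SpeciesKind.MIRNA, Compartment.CYTOPLASM))

            enzymes = [gid]
            inhibitors: list[Inhibitor] = []
            if mid in tfmir:
                for tf_id, regulation, _pubmed in tfmir[mid]:
                    if tf_id not in ext.species:
                        continue
                    if regulation == "activation":
                        enzymes.append(tf_id)
                    else:
                        inhibitors.append(Inhibitor(ref=tf_id, ikd=repressor_ikd))
            n_activating = len(enzymes) - 1  # all enzymes beyond the gene template
            ext.add_reaction(
                Reaction(
                    id=f"tx:miRgene:{mid}",
                    rtype=ReactionType.TRANSCRIPTION,
                    products=[nuc],
                    enzymes=enzymes,
                    inhibitors=inhibitors,
                    k=k,
                    ekd=tf_ekd**n_activating if n_activating else None,
                )
            )
            ext.add_reaction(
                Reaction(
                    id=f"tl:miR:{mid}",
                    rtype=ReactionType.TRANSLOCATION,
                    reactants=[nuc],
                    products=[cyt],
                    k=2 * k,
                )
            )
        for mrna in mrnas:
            cx = f"cx:{mid}:{mrna}"
            if cx in ext.species:
                continue
            ext.add_species(Species(cx, cx, SpeciesKind.COMPLEX, Compartment.CYTOPLASM))
            ext.add_reaction(
                Reaction(
                    id=f"bind:{mid}:{mrna}",
                    rtype=ReactionType.MIRNA_BINDING,
                    reactants=[cyt, mrna],
                    products=[cx],
                    k=2 * k,
                )
            )
            ext.add_reaction(
                Reaction(
                    id=f"dec:cx:{mid}:{mrna}",
                    rtype=ReactionType.DECAY,
                    reactants=[cx],
                    k=k_complex_decay,
                )
            )

    ext.sort_reactions()
    ext.validate()
    return ext
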