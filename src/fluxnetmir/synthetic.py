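"""Seeded generators: toy models, regulation tables and cohorts.

Real inputs to this kind of analysis — a curated signaling model, validated
miRNA-target tables and per-individual expression profiles — are external
and large. This module generates miniature stand-ins with the statistical
structure the analysis assumes, so that every pipeline stage is testable
without downloads. It is explicitly synthetic: expression noise is
log-normal (non-negative, right-skewed), pathway wiring is a caricature.

The toy model is a star of linear cascades feeding one ``proliferation``
hallmark pseudo-object:

* one *kinase* gene (the planted drug target) whose protein catalyzes the
  phospho-route;
* *pathway* genes whose proteins reach the hallmark only via
  kinase-catalyzed phosphorylation (drug-sensitive route);
* *background* genes whose proteins activate the hallmark directly
  (drug-insensitive route).

Every protein also decays, so inhibiting the kinase re-routes pathway
tokens into decay instead of the hallmark — the hallmark's steady level
then falls with dose instead of merely arriving later. Cohorts plant
responder structure: responders carry elevated kinase/pathway expression
and lowered hallmark-repressing miRNAs, non-responders the baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .drugs import DrugSpec, DrugTarget
from .expression import ExpressionProfile
from .mirao import MiRTTable, TFmiRTable
from .model import (
    Compartment,
    ModelCensus,
    MolecularModel,
    Reaction,
    ReactionType,
    Species,
    SpeciesKind,
)

__all__ = [
    "FixtureSpec",
    "gen_toy_model",
    "gen_mir_tables",
    "gen_cohort",
    "planted_drug",
    "MIRAO_K",
]

# Cascade kinetics (token units per step). Two constraints shape these:
# per-step transfers stay small against pool sizes (quasi-continuous
# dynamics, no guard-driven limit cycles) and every downstream equilibrium
# sits strictly below its firing guard (transcription slower than
# translation, decays faster than production), so the steady-state
# detector actually triggers. The hallmark carries a strong decay: its
# level then tracks incoming flux, which is what treatment perturbs.
K_TX = 0.005
K_TL = 0.01
K_PH = 0.0005
K_ACT = 0.005
K_PDECAY = 0.02
K_HALLMARK_DECAY = 0.5

#: kinetic parameter for reactions created by the miR-add-on in fixtures,
#: scaled to the cascade constants above
MIRAO_K = 0.002

BASE_GENE_EXPR = 10.0
BASE_MIRNA_EXPR = 8.0

#: iKd (nM) of the planted drug; at the default administered concentration
#: of 1 token unit the inhibition factor is iKd/[I] = 0.1
PLANTED_IKD = 0.1


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a generated study.

    chain_depth 3 builds gene→mRNA→protein→hallmark cascades; depth 4 (the
    default) inserts the kinase-catalyzed phosphorylation stage that makes
    the drug target meaningful. ``effect_size`` is the multiplicative
    separation between responder and non-responder pathway activity;
    ``noise_sd`` the log-scale standard deviation of expression noise.
    """

    seed: int = 0
    n_genes: int = 5
    n_mirnas: int = 2
    chain_depth: int = 4
    drug_target_gene: str | None = None
    effect_size: float = 4.0
    noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_mirnas < 0:
            raise ValueError("n_mirnas must be >= 0")
        if self.chain_depth not in (3, 4):
            raise ValueError("chain_depth must be 3 or 4")
        if self.effect_size <= 0 or self.noise_sd < 0:
            raise ValueError("effect_size must be > 0 and noise_sd >= 0")

    # --- deterministic naming -------------------------------------------
    def gene_ids(self) -> list[str]:
        return [f"ENSG{i + 1:011d}" for i in range(self.n_genes)]

    @property
    def kinase_gene(self) -> str:
        return self.drug_target_gene or self.gene_ids()[0]

    def pathway_genes(self) -> list[str]:
        """Genes routed through the kinase (includes the kinase's own cascade)."""
        genes = self.gene_ids()
        if self.n_genes == 1:
            return genes
        others = [g for g in genes if g != self.kinase_gene]
        n_path = math.ceil(len(others) / 2)
        return [self.kinase_gene] + others[:n_path]

    def background_genes(self) -> list[str]:
        path = set(self.pathway_genes())
        return [g for g in self.gene_ids() if g not in path]


def mrna_id(gene: str) -> str:
    return f"mRNA:{gene}"


def protein_id(gene: str) -> str:
    return f"prot:{gene}"


def phospho_id(gene: str) -> str:
    return f"P-prot:{gene}"


def planted_drug(spec: FixtureSpec) -> DrugSpec:
    """The synthetic inhibitor of the fixture's kinase protein."""
    return DrugSpec("plantinib", (DrugTarget(protein_id(spec.kinase_gene), PLANTED_IKD),))


def gen_toy_model(spec: FixtureSpec) -> tuple[MolecularModel, ModelCensus]:
    """Build the toy model and an independently book-kept census tally.

    The tally is computed from the closed-form construction counts, not by
    inspecting the model, so it can serve as an oracle for ``census``.
    """
    m = MolecularModel(readouts=["proliferation"])
    m.add_species(
        Species("proliferation", "proliferation", SpeciesKind.PSEUDO_OBJECT, Compartment.CYTOPLASM)
    )
    m.add_reaction(
        Reaction(
            id="dec:proliferation",
            rtype=ReactionType.DECAY,
            reactants=["proliferation"],
            k=K_HALLMARK_DECAY,
        )
    )
    genes = spec.gene_ids()
    pathway = set(spec.pathway_genes()) if spec.chain_depth >= 4 else set()
    kin_prot = protein_id(spec.kinase_gene)
    for g in genes:
        mr, pr = mrna_id(g), protein_id(g)
        m.add_species(Species(g, g, SpeciesKind.GENE, Compartment.NUCLEUS))
        m.add_species(Species(mr, mr, SpeciesKind.MRNA, Compartment.CYTOPLASM))
        m.add_species(Species(pr, pr, SpeciesKind.PROTEIN, Compartment.CYTOPLASM))
        m.add_reaction(
            Reaction(
                id=f"tx:{g}",
                rtype=ReactionType.TRANSCRIPTION,
                enzymes=[g],  # gene is a non-consumed template
                products=[mr],
                k=K_TX,
            )
        )
        m.add_reaction(
            Reaction(
                id=f"tl:{g}", rtype=ReactionType.TRANSLATION, reactants=[mr], products=[pr], k=K_TL
            )
        )
        m.add_reaction(
            Reaction(id=f"dcp:{g}", rtype=ReactionType.DECAY, reactants=[pr], k=K_PDECAY)
        )
        if g in pathway:
            pp = phospho_id(g)
            m.add_species(Species(pp, pp, SpeciesKind.PROTEIN, Compartment.CYTOPLASM))
            m.add_reaction(
                Reaction(
                    id=f"ph:{g}",
                    rtype=ReactionType.PHOSPHORYLATION,
                    reactants=[pr],
                    products=[pp],
                    enzymes=[kin_prot],
                    k=K_PH,
                )
            )
            m.add_reaction(
                Reaction(
                    id=f"act:{g}",
                    rtype=ReactionType.ACTIVATION,
                    reactants=[pp],
                    products=["proliferation"],
                    k=K_ACT,
                )
            )
        else:
            m.add_reaction(
                Reaction(
                    id=f"act:{g}",
                    rtype=ReactionType.ACTIVATION,
                    reactants=[pr],
                    products=["proliferation"],
                    k=K_ACT,
                )
            )
    m.sort_reactions()
    m.validate()

    n = spec.n_genes
    n_path = len(pathway)
    tally = ModelCensus(
        species_counts={
            SpeciesKind.GENE: n,
            SpeciesKind.MRNA: n,
            SpeciesKind.PROTEIN: n + n_path,  # proteins + phospho-forms
            SpeciesKind.MIRNA: 0,
            SpeciesKind.COMPLEX: 0,
            SpeciesKind.COMPOUND: 0,
            SpeciesKind.PSEUDO_OBJECT: 1,
            SpeciesKind.SIRNA: 0,
        },
        reaction_counts={
            ReactionType.TRANSCRIPTION: n,
            ReactionType.TRANSLATION: n,
            ReactionType.DECAY: n + 1,
            ReactionType.COMPLEX_FORMATION: 0,
            ReactionType.TRANSLOCATION: 0,
            ReactionType.PHOSPHORYLATION: n_path,
            ReactionType.DEPHOSPHORYLATION: 0,
            ReactionType.ACTIVATION: n,
            ReactionType.MIRNA_BINDING: 0,
        },
        n_species=3 * n + n_path + 1,
        n_reactions=4 * n + n_path + 1,
    )
    return m, tally


def gen_mir_tables(spec: FixtureSpec) -> tuple[MiRTTable, TFmiRTable]:
    """miRT/TFmiR tables wired against the companion toy model.

    Every miRNA targets at least one pathway gene (so all generated miRNAs
    are hallmark-repressing); a seeded subset additionally gets a TF drawn
    from the background genes, alternating activation/repression.
    """
    rng = np.random.default_rng(spec.seed)
    mirt = MiRTTable()
    tfmir = TFmiRTable()
    if spec.n_mirnas == 0:
        return mirt, tfmir
    pathway = spec.pathway_genes() if spec.chain_depth >= 4 else spec.gene_ids()
    background = spec.background_genes()
    for j in range(spec.n_mirnas):
        mir = f"mir-{101 + j}"
        gene = pathway[j % len(pathway)]
        pubmed = str(17000000 + int(rng.integers(0, 10**6)))
        mirt.add(gene, mir, pubmed)
        if background and rng.random() < 0.5:
            tf = background[int(rng.integers(0, len(background)))]
            regulation = "activation" if j % 2 == 0 else "repression"
            tfmir.add(mir, tf, regulation, str(17000000 + int(rng.integers(0, 10**6))))
    return mirt, tfmir


def gen_cohort(
    spec: FixtureSpec, n_responders: int, n_nonresponders: int
) -> list[tuple[ExpressionProfile, ExpressionProfile, str]]:
    """Expression profiles with planted responder structure.

    Responders carry kinase/pathway gene expression elevated by
    ``effect_size`` and hallmark-repressing miRNA expression lowered by the
    same factor; both groups share the log-normal noise model. With
    ``effect_size = 1`` the two groups are exchangeable (null).
    """
    rng = np.random.default_rng(spec.seed)
    pathway = set(spec.pathway_genes()) if spec.chain_depth >= 4 else set(spec.gene_ids())
    mirnas = [f"mir-{101 + j}" for j in range(spec.n_mirnas)]
    cohort: list[tuple[ExpressionProfile, ExpressionProfile, str]] = []
    labels = ["responder"] * n_responders + ["non-responder"] * n_nonresponders
    for i, label in enumerate(labels):
        boost = spec.effect_size if label == "responder" else 1.0
        genes = {}
        for g in spec.gene_ids():
            mu = BASE_GENE_EXPR * (boost if g in pathway else 1.0)
            genes[g] = mu * math.exp(rng.normal(0.0, spec.noise_sd))
        mirs = {}
        for mir in mirnas:
            mu = BASE_MIRNA_EXPR / boost
            mirs[mir] = mu * math.exp(rng.normal(0.0, spec.noise_sd))
        sample = f"S{i + 1:03d}"
        cohort.append(
            (
                ExpressionProfile(values=genes, label=sample),
                ExpressionProfile(values=mirs, label=sample),
                label,
            )
        )
    return cohort
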