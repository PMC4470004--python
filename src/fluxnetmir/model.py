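"""Typed in-memory Petri-net model with XML serialization and census reporting.

A :class:`MolecularModel` is a bipartite place/transition net: species are
token-carrying places (genes, mRNAs, proteins, miRNAs, complexes, compounds,
hallmark pseudo-objects, siRNAs) and reactions are guarded transitions typed
by the biochemical process they represent. Models are stored in a small
SBML-like XML dialect so that an importer for other model files can be added
without touching this core.

Conventions baked into the dialect:

* Genes are transcription *templates*: a transcription reaction lists its
  gene under ``enzyme`` (non-consumed), not ``reactant``, because gene
  species carry expression levels that drive flux continuously.
* Reactions are kept sorted lexicographically by id. The simulation engine
  applies sequential in-place updates, so a pinned total order is required
  for reproducibility.
"""

from __future__ import annotations

import copy
import enum
import os
from dataclasses import dataclass, field

from lxml import etree

__all__ = [
    "SpeciesKind",
    "Compartment",
    "ReactionType",
    "Species",
    "Inhibitor",
    "Reaction",
    "MolecularModel",
    "ModelCensus",
    "ModelParseError",
    "ModelValidationError",
    "ModelPartition",
    "read_model",
    "write_model",
    "partition_by_type",
    "census",
]


class SpeciesKind(str, enum.Enum):
    """Component taxonomy of the network."""

    GENE = "gene"
    MRNA = "mRNA"
    PROTEIN = "protein"
    MIRNA = "miRNA"
    COMPLEX = "complex"
    COMPOUND = "compound"
    PSEUDO_OBJECT = "pseudo-object"
    SIRNA = "siRNA"


class Compartment(str, enum.Enum):
    NUCLEUS = "nucleus"
    CYTOPLASM = "cytoplasm"
    MEMBRANE = "membrane"
    EXTRACELLULAR = "extracellular"


class ReactionType(str, enum.Enum):
    TRANSCRIPTION = "transcription"
    TRANSLATION = "translation"
    DECAY = "decay"
    COMPLEX_FORMATION = "complex-formation"
    TRANSLOCATION = "translocation"
    PHOSPHORYLATION = "phosphorylation"
    DEPHOSPHORYLATION = "dephosphorylation"
    ACTIVATION = "activation"
    MIRNA_BINDING = "miRNA-binding"


class ModelParseError(ValueError):
    """Raised for malformed model XML; message names the offending line."""


class ModelValidationError(ValueError):
    """Raised when a structurally well-formed model violates an invariant."""


@dataclass
class Species:
    """A token-carrying place of the net.

    ``concentration`` is in arbitrary token units (expression values are
    used directly as initial token counts). It must stay non-negative; the
    kind of a species is immutable after creation.
    """

    id: str
    name: str
    kind: SpeciesKind
    compartment: Compartment
    concentration: float = 0.0

    def __post_init__(self) -> None:
        self.kind = SpeciesKind(self.kind)
        self.compartment = Compartment(self.compartment)
        if not self.id:
            raise ModelValidationError("species id must be non-empty")
        if self.concentration < 0:
            raise ModelValidationError(
                f"species {self.id!r}: concentration must be >= 0, got {self.concentration}"
            )
        self.__dict__["_sealed"] = True

    def __setattr__(self, attr: str, value) -> None:
        if attr == "kind" and self.__dict__.get("_sealed"):
            raise AttributeError(f"species {self.id!r}: kind is immutable")
        super().__setattr__(attr, value)


@dataclass
class Inhibitor:
    """An inhibitor annotation on a reaction.

    ``ref`` is either a species id (concentration looked up in the model
    state) or an external name such as a drug, in which case ``conc`` holds
    its fixed concentration in token units. ``ikd`` is the inhibitor
    dissociation constant in nM; the rate factor contributed is
    ``ikd / [I]`` whenever ``[I] > 0``.
    """

    ref: str
    ikd: float
    conc: float | None = None

    def __post_init__(self) -> None:
        if self.ikd <= 0:
            raise ModelValidationError(f"inhibitor {self.ref!r}: iKd must be > 0")


@dataclass
class Reaction:
    """A typed guarded transition.

    ``reactants`` are consumed, ``products`` produced, ``enzymes`` are
    catalysts/templates (rate factors, never consumed). ``k`` is the kinetic
    parameter; ``ekd`` the optional enzymatic dissociation constant (divides
    the speed; treated as 1 when absent, so the inhibition law degenerates
    to plain mass action).
    """

    id: str
    rtype: ReactionType
    reactants: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    enzymes: list[str] = field(default_factory=list)
    inhibitors: list[Inhibitor] = field(default_factory=list)
    k: float = 0.01
    ekd: float | None = None

    def __post_init__(self) -> None:
        self.rtype = ReactionType(self.rtype)
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if self.k <= 0:
            raise ModelValidationError(f"reaction {self.id!r}: k must be > 0, got {self.k}")
        if self.ekd is not None and self.ekd <= 0:
            raise ModelValidationError(f"reaction {self.id!r}: eKd must be > 0")


@dataclass
class ModelCensus:
    """Per-kind species counts and per-rtype reaction counts."""

    species_counts: dict[SpeciesKind, int]
    reaction_counts: dict[ReactionType, int]
    n_species: int
    n_reactions: int

    def __post_init__(self) -> None:
        assert sum(self.species_counts.values()) == self.n_species
        assert sum(self.reaction_counts.values()) == self.n_reactions


@dataclass
class ModelPartition:
    """Jointly exhaustive, mutually exclusive component arrays."""

    species_by_kind: dict[SpeciesKind, list[Species]]
    reactions_by_rtype: dict[ReactionType, list[Reaction]]


@dataclass
class MolecularModel:
    """The Petri net: species map, ordered reaction list, hallmark readouts.

    ``readouts`` lists pseudo-object species ids designated as hallmark
    accumulators (e.g. ``'proliferation'``).
    """

    species: dict[str, Species] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)
    readouts: list[str] = field(default_factory=list)

    def add_species(self, sp: Species) -> Species:
        if sp.id in self.species:
            raise ModelValidationError(f"duplicate species id {sp.id!r}")
        self.species[sp.id] = sp
        return sp

    def add_reaction(self, rx: Reaction) -> Reaction:
        if any(r.id == rx.id for r in self.reactions):
            raise ModelValidationError(f"duplicate reaction id {rx.id!r}")
        self.reactions.append(rx)
        return rx

    def sort_reactions(self) -> None:
        """Pin the reaction order (lexicographic by id)."""
        self.reactions.sort(key=lambda r: r.id)

    def copy(self) -> "MolecularModel":
        return copy.deepcopy(self)

    def validate(self) -> None:
        """Check cross-references, readout typing and numeric invariants."""
        for rx in self.reactions:
            for ref in (*rx.reactants, *rx.products, *rx.enzymes):
                if ref not in self.species:
                    raise ModelValidationError(
                        f"reaction {rx.id!r} references unknown species {ref!r}"
                    )
        for rid in self.readouts:
            if rid not in self.species:
                raise ModelValidationError(f"readout {rid!r} is not a model species")
            if self.species[rid].kind is not SpeciesKind.PSEUDO_OBJECT:
                raise ModelValidationError(
                    f"readout {rid!r} must be a pseudo-object, got {self.species[rid].kind.value}"
                )
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ModelValidationError("duplicate reaction ids")


def _fmt(x: float) -> str:
    """Shortest decimal literal that round-trips through float()."""
    return repr(float(x))


def write_model(model: MolecularModel, destination=None) -> bytes:
    """Serialize ``model`` to the canonical XML dialect.

    The output is deterministic: species and readouts sorted by id,
    reactions in pinned id order, fixed attribute order, UTF-8. Returns the
    document bytes; if ``destination`` (path or binary file-like) is given,
    also writes them there.
    """
    root = etree.Element("molecularModel")
    lor = etree.SubElement(root, "listOfReadouts")
    for rid in sorted(model.readouts):
        etree.SubElement(lor, "readout", species=rid)
    los = etree.SubElement(root, "listOfSpecies")
    for sid in sorted(model.species):
        sp = model.species[sid]
        etree.SubElement(
            los,
            "species",
            id=sp.id,
            name=sp.name,
            kind=sp.kind.value,
            compartment=sp.compartment.value,
            initialConcentration=_fmt(sp.concentration),
        )
    lorx = etree.SubElement(root, "listOfReactions")
    for rx in sorted(model.reactions, key=lambda r: r.id):
        attrs = {"id": rx.id, "rtype": rx.rtype.value, "k": _fmt(rx.k)}
        if rx.ekd is not None:
            attrs["eKd"] = _fmt(rx.ekd)
        el = etree.SubElement(lorx, "reaction", **attrs)
        for ref in rx.reactants:
            etree.SubElement(el, "reactant", species=ref)
        for ref in rx.products:
            etree.SubElement(el, "product", species=ref)
        for ref in rx.enzymes:
            etree.SubElement(el, "enzyme", species=ref)
        for inh in rx.inhibitors:
            iattrs = {"species": inh.ref, "iKd": _fmt(inh.ikd)}
            if inh.conc is not None:
                iattrs["conc"] = _fmt(inh.conc)
            etree.SubElement(el, "inhibitor", **iattrs)
    doc = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(doc)
        else:
            with open(destination, "wb") as fh:
                fh.write(doc)
    return doc


def _req(el, attr: str):
    v = el.get(attr)
    if v is None:
        raise ModelParseError(
            f"element <{el.tag}> at line {el.sourceline}: missing attribute {attr!r}"
        )
    return v


def read_model(xml_source) -> MolecularModel:
    """Parse a model document (path, bytes, or file-like) and validate it.

    Raises :class:`ModelParseError` for malformed XML (message names the
    line) and :class:`ModelValidationError` for dangling references or
    unknown kind/rtype values. The returned model has its reaction list in
    pinned id order.
    """
    try:
        if isinstance(xml_source, bytes):
            root = etree.fromstring(xml_source)
        elif isinstance(xml_source, str) and xml_source.lstrip().startswith("<"):
            root = etree.fromstring(xml_source.encode())
        elif hasattr(xml_source, "read"):
            root = etree.parse(xml_source).getroot()
        else:
            root = etree.parse(os.fspath(xml_source)).getroot()
    except etree.XMLSyntaxError as exc:  # lxml message carries "line N"
        raise ModelParseError(f"malformed model XML: {exc}") from exc

    model = MolecularModel()
    for el in root.iterfind("listOfSpecies/species"):
        kind = _req(el, "kind")
        try:
            kind = SpeciesKind(kind)
        except ValueError:
            raise ModelValidationError(f"unknown species kind {kind!r} (line {el.sourceline})")
        comp = _req(el, "compartment")
        try:
            comp = Compartment(comp)
        except ValueError:
            raise ModelValidationError(f"unknown compartment {comp!r} (line {el.sourceline})")
        model.add_species(
            Species(
                id=_req(el, "id"),
                name=el.get("name", _req(el, "id")),
                kind=kind,
                compartment=comp,
                concentration=float(el.get("initialConcentration", "0")),
            )
        )
    for el in root.iterfind("listOfReactions/reaction"):
        rt = _req(el, "rtype")
        try:
            rt = ReactionType(rt)
        except ValueError:
            raise ModelValidationError(f"unknown reaction type {rt!r} (line {el.sourceline})")
        ekd = el.get("eKd")
        rx = Reaction(
            id=_req(el, "id"),
            rtype=rt,
            reactants=[_req(c, "species") for c in el.iterfind("reactant")],
            products=[_req(c, "species") for c in el.iterfind("product")],
            enzymes=[_req(c, "species") for c in el.iterfind("enzyme")],
            inhibitors=[
                Inhibitor(
                    ref=_req(c, "species"),
                    ikd=float(_req(c, "iKd")),
                    conc=float(c.get("conc")) if c.get("conc") is not None else None,
                )
                for c in el.iterfind("inhibitor")
            ],
            k=float(_req(el, "k")),
            ekd=float(ekd) if ekd is not None else None,
        )
        model.add_reaction(rx)
    model.readouts = [_req(el, "species") for el in root.iterfind("listOfReadouts/readout")]
    model.sort_reactions()
    model.validate()
    return model


def partition_by_type(model: MolecularModel) -> ModelPartition:
    """Split the model into per-kind species arrays and per-rtype reaction arrays.

    Arrays are jointly exhaustive and mutually exclusive; each preserves the
    model's own ordering (species insertion order, pinned reaction order).
    """
    sp: dict[SpeciesKind, list[Species]] = {k: [] for k in SpeciesKind}
    for s in model.species.values():
        sp[s.kind].append(s)
    rx: dict[ReactionType, list[Reaction]] = {t: [] for t in ReactionType}
    for r in model.reactions:
        rx[r.rtype].append(r)
    return ModelPartition(species_by_kind=sp, reactions_by_rtype=rx)


def census(model: MolecularModel) -> ModelCensus:
    """Component/reaction summary: counts per kind and per reaction type."""
    part = partition_by_type(model)
    return ModelCensus(
        species_counts={k: len(v) for k, v in part.species_by_kind.items()},
        reaction_counts={t: len(v) for t, v in part.reactions_by_rtype.items()},
        n_species=len(model.species),
        n_reactions=len(model.reactions),
    )
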