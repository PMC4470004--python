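"""Independent reference implementations used as test oracles.

The naive simulator here is written against the published update rule
directly — dict-based, one literal line per rule clause — and must stay
independent of the package's engine internals. Random-net generation for
the oracle-equivalence tests also lives here.
"""

from __future__ import annotations

import random

from fluxnetmir.model import (
    Compartment,
    Inhibitor,
    MolecularModel,
    Reaction,
    ReactionType,
    Species,
    SpeciesKind,
)


def naive_speed(rx, conc: dict[str, float]) -> float:
    """S = k * C_a * C_e * (iKd/[I]) / eKd, product over multiples."""
    s = rx.k
    for a in rx.reactants:
        s = s * conc[a]
    for e in rx.enzymes:
        s = s * conc[e]
    for inh in rx.inhibitors:
        if inh.ref in conc:
            ci = conc[inh.ref]
        elif inh.conc is not None:
            ci = inh.conc
        else:
            ci = 0.0
        if ci > 0:
            s = s * (inh.ikd / ci)
    if rx.ekd is not None:
        s = s / rx.ekd
    return s


def naive_step(model: MolecularModel, conc: dict[str, float]) -> dict[str, float]:
    """One sweep: reactions in id order, sequential in-place updates.

    A reaction fires iff C_p < C_a and S < 0.75 * C_a, with C_a the
    limiting reactant (the limiting enzyme for source reactions) and C_p
    the limiting product (0 when there are no products).
    """
    conc = dict(conc)
    for rx in sorted(model.reactions, key=lambda r: r.id):
        s = naive_speed(rx, conc)
        if rx.reactants:
            c_a = min(conc[a] for a in rx.reactants)
        elif rx.enzymes:
            c_a = min(conc[e] for e in rx.enzymes)
        else:
            continue
        if rx.products:
            c_p = min(conc[p] for p in rx.products)
        else:
            c_p = 0.0
        if c_p < c_a and s < c_a * 0.75:
            for a in rx.reactants:
                conc[a] = conc[a] - s
            for p in rx.products:
                conc[p] = conc[p] + s
    return conc


def naive_trajectory(model: MolecularModel, n_steps: int) -> list[dict[str, float]]:
    conc = {sid: sp.concentration for sid, sp in model.species.items()}
    out = [dict(conc)]
    for _ in range(n_steps):
        conc = naive_step(model, conc)
        out.append(dict(conc))
    return out


_KINDS = list(SpeciesKind)
_COMPARTMENTS = list(Compartment)
_RTYPES = list(ReactionType)


def random_net(rng: random.Random, max_species: int = 6, max_reactions: int = 5) -> MolecularModel:
    """A small random net exercising every speed-law clause.

    Species get random kinds/compartments and concentrations in [0, 20];
    reactions get 0-2 reactants (distinct), 0-2 products, 0-1 enzymes,
    occasional inhibitors (species-backed or fixed-concentration) and an
    occasional eKd.
    """
    n_sp = rng.randint(2, max_species)
    model = MolecularModel()
    sids = [f"s{i}" for i in range(n_sp)]
    for sid in sids:
        model.add_species(
            Species(
                id=sid,
                name=sid.upper(),
                kind=rng.choice(_KINDS),
                compartment=rng.choice(_COMPARTMENTS),
                concentration=round(rng.uniform(0.0, 20.0), 6),
            )
        )
    n_rx = rng.randint(1, max_reactions)
    for i in range(n_rx):
        reactants = rng.sample(sids, rng.randint(0, min(2, n_sp)))
        products = rng.sample(sids, rng.randint(0, min(2, n_sp)))
        enzymes = rng.sample(sids, rng.randint(0, 1))
        if not reactants and not enzymes:
            enzymes = [rng.choice(sids)]
        inhibitors = []
        if rng.random() < 0.4:
            if rng.random() < 0.5:
                inhibitors.append(Inhibitor(ref=rng.choice(sids), ikd=rng.uniform(0.1, 5.0)))
            else:
                inhibitors.append(
                    Inhibitor(
                        ref=f"drug{i}",
                        ikd=rng.uniform(0.1, 5.0),
                        conc=rng.choice([0.0, rng.uniform(0.1, 4.0)]),
                    )
                )
        model.add_reaction(
            Reaction(
                id=f"r{i}",
                rtype=rng.choice(_RTYPES),
                reactants=reactants,
                products=products,
                enzymes=enzymes,
                inhibitors=inhibitors,
                k=round(rng.uniform(0.001, 0.5), 6),
                ekd=round(rng.uniform(0.5, 4.0), 6) if rng.random() < 0.3 else None,
            )
        )
    model.sort_reactions()
    model.validate()
    return model


def tmm_reference(counts, ref_col, trim_m=0.30, trim_a=0.05):
    """Straightforward loop-based TMM factors (unnormalized, vs a fixed ref).

    Independent of the package implementation: explicit per-gene loops,
    sort-based trimming instead of ranks.
    """
    import math

    lib = {c: float(counts[c].sum()) for c in counts.columns}
    out = {}
    for col in counts.columns:
        if col == ref_col:
            out[col] = 1.0
            continue
        rows = []
        for g in counts.index:
            yk, yr = float(counts.at[g, col]), float(counts.at[g, ref_col])
            if yk <= 0 or yr <= 0:
                continue
            fk, fr = yk / lib[col], yr / lib[ref_col]
            m = math.log2(fk / fr)
            a = 0.5 * math.log2(fk * fr)
            v = (lib[col] - yk) / (lib[col] * yk) + (lib[ref_col] - yr) / (lib[ref_col] * yr)
            rows.append((m, a, v))
        n = len(rows)
        by_m = sorted(r[0] for r in rows)
        by_a = sorted(r[1] for r in rows)
        lo = int(math.floor(n * trim_m))
        lo_a = int(math.floor(n * trim_a))
        m_lo, m_hi = by_m[lo], by_m[n - 1 - lo]
        a_lo, a_hi = by_a[lo_a], by_a[n - 1 - lo_a]
        num = den = 0.0
        for m, a, v in rows:
            if m_lo <= m <= m_hi and a_lo <= a <= a_hi:
                num += m / v
                den += 1.0 / v
        out[col] = 2 ** (num / den) if den else 1.0
    return out
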