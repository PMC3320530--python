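"""Marker category assignment (C1-C8) from call rate, the discovery
genotype, F1-progeny segregation and germplasm polymorphism.

The classifier works on *array-observable* states: a null heterozygote
is indistinguishable from the homozygote it resembles, so ``A0``
collapses to ``AA`` before any model is fitted.  Null alleles are
revealed only through segregation (unexpected homozygous-like or ``00``
progeny classes) or through ``00`` clusters in the germplasm.

Categories
----------
C1  call-rate failure (proxy for un-clusterable intensity data)
C2  expected segregation of the heterozygous discovery genotype
C3  heterozygous discovery genotype, segregation reveals a null allele
    in the other parent (0B×AB or 00×AB patterns)
C4  heterozygous null in the discovery genotype itself (00×0A pattern)
C5  no segregation; SNP polymorphism in the germplasm
C6  no segregation; null-allele presence/absence polymorphism only
C7  monomorphic heterozygous-like everywhere (suspected duplicated
    locus; a heterozygous-like haploid control confirms)
C8  monomorphic
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from citrus_snp.genotype_io import (
    GenotypeMatrix, MarkerRecord, PopulationScheme,
    AA, AB, BB, NULL2, MISSING, observable_codes,
)

#: Observable progeny states per model, with expected proportions.
#: States are observable codes; gamete enumeration collapses null
#: heterozygotes onto the matching homozygote class.
SEGREGATION_MODELS: dict[str, dict[int, float]] = {
    # AB × AA -> AA:AB = 1:1
    "ABxAA": {AA: 0.5, AB: 0.5},
    "ABxBB": {BB: 0.5, AB: 0.5},
    # AB × AB -> 1:2:1
    "ABxAB": {AA: 0.25, AB: 0.5, BB: 0.25},
    # AB × A0 -> gametes (A,B)x(A,0): AA, A0->AA-like, AB, B0->BB-like
    "ABxA0": {AA: 0.5, AB: 0.25, BB: 0.25},
    "ABxB0": {BB: 0.5, AB: 0.25, AA: 0.25},
    # AB × 00 -> A0, B0 -> homozygous-like 1:1
    "ABx00": {AA: 0.5, BB: 0.5},
    # 0A × 00 -> A0->AA-like, 00 = 1:1 (discovery null-het)
    "A0x00": {AA: 0.5, NULL2: 0.5},
    "B0x00": {BB: 0.5, NULL2: 0.5},
    # both parents null-het
    "A0xA0": {AA: 0.75, NULL2: 0.25},
    "B0xB0": {BB: 0.75, NULL2: 0.25},
    "A0xB0": {AA: 0.25, AB: 0.25, BB: 0.25, NULL2: 0.25},
}

#: Models implying a null allele somewhere in the cross.
NULL_MODELS = {"ABxA0", "ABxB0", "ABx00", "A0x00", "B0x00",
               "A0xA0", "B0xB0", "A0xB0"}


@dataclass
class SegregationTest:
    """Chi-square goodness-of-fit of observed progeny classes against
    each candidate expected-ratio hypothesis."""
    counts: dict[int, int]
    n_typed: int
    p_values: dict[str, float]
    best_model: str              # model name or "none"
    best_p: float = 0.0
    statistic: float = float("nan")


def test_segregation(progeny_obs: np.ndarray,
                     models: list[str] | None = None,
                     alpha: float = 0.01,
                     min_typed: int = 10) -> SegregationTest:
    """Fit candidate segregation models to observable progeny states at
    one locus.

    A model is admissible only if every observed state belongs to its
    state space; otherwise its p-value is 0.  The best model maximizes
    the p-value; ties prefer a model without null alleles (parsimony).
    Returns best_model "none" when every model is rejected at `alpha`.
    """
    typed = progeny_obs[progeny_obs != MISSING]
    if typed.size < min_typed:
        raise ValueError(f"need >= {min_typed} typed progeny, "
                         f"got {typed.size}")
    states, counts = np.unique(typed, return_counts=True)
    observed = dict(zip((int(s) for s in states), (int(c) for c in counts)))
    names = models if models is not None else list(SEGREGATION_MODELS)
    pvals: dict[str, float] = {}
    stats_: dict[str, float] = {}
    for name in names:
        expected = SEGREGATION_MODELS[name]
        if any(s not in expected for s in observed):
            pvals[name] = 0.0
            stats_[name] = float("inf")
            continue
        keys = sorted(expected)
        obs_v = np.array([observed.get(k, 0) for k in keys], dtype=float)
        exp_v = np.array([expected[k] for k in keys]) * obs_v.sum()
        chi2, p = stats.chisquare(obs_v, exp_v)
        pvals[name] = float(p)
        stats_[name] = float(chi2)
    # max p; ties broken toward null-free models, then name for stability
    best = max(pvals,
               key=lambda m: (pvals[m], m not in NULL_MODELS, m))
    if pvals[best] < alpha:
        return SegregationTest(observed, int(typed.size), pvals, "none")
    return SegregationTest(observed, int(typed.size), pvals, best,
                           best_p=pvals[best], statistic=stats_[best])


_MODELS_FOR_DISCOVERY_HET = ["ABxAA", "ABxBB", "ABxAB", "ABxA0", "ABxB0",
                             "ABx00"]


@dataclass
class LocusClassification:
    locus_id: str
    category: str
    best_model: str = ""
    p_value: float = float("nan")
    call_rate: float = 1.0
    note: str = ""


def classify_locus(gm: GenotypeMatrix, locus_id: str,
                   scheme: PopulationScheme, discovery_accession: str,
                   haploid_control: str | None = None,
                   call_rate_threshold: float = 0.8,
                   alpha: float = 0.01,
                   min_typed: int = 10) -> LocusClassification:
    """Assign one locus to a category C1-C8 (see module docstring).

    The decision tree inspects, in order: overall call rate (C1); the
    discovery accession's observable genotype with progeny segregation
    (C2/C3/C4); and, absent segregation, germplasm polymorphism
    (C5/C6/C7/C8).  Conflicting evidence yields ``unassigned`` with a
    diagnostic note rather than a silent guess.
    """
    j = gm.loc_idx(locus_id)
    obs = observable_codes(gm.calls[:, j])
    call_rate = float((obs != MISSING).mean())
    if call_rate < call_rate_threshold:
        return LocusClassification(locus_id, "C1", call_rate=call_rate,
                                   note="call rate below threshold")

    idx = {a: i for i, a in enumerate(gm.accession_ids)}
    germ_rows = [idx[a] for a in scheme.germplasm if a in idx]
    par_rows = [idx[a] for a in scheme.accessions_with_role("parent_female")
                + scheme.accessions_with_role("parent_male") if a in idx]
    prog_rows = [idx[a] for a in scheme.accessions_with_role("progeny")
                 if a in idx]
    disc = int(obs[idx[discovery_accession]])
    prog = obs[prog_rows] if prog_rows else np.array([], dtype=np.int8)
    n_typed_prog = int((prog != MISSING).sum())
    germ = obs[germ_rows + par_rows]
    germ_typed = germ[germ != MISSING]
    germ_has_null = bool((germ_typed == NULL2).any())
    typed_all = obs[obs != MISSING]

    # fixed heterozygous-like everywhere: suspected duplicated locus
    if typed_all.size > 0 and (typed_all == AB).all():
        note = "fixed heterozygous-like pattern"
        if haploid_control is not None \
                and int(obs[idx[haploid_control]]) == AB:
            note = ("haploid control heterozygous-like: duplication "
                    "confirmed")
        return LocusClassification(locus_id, "C7", call_rate=call_rate,
                                   note=note)

    if disc == AB and n_typed_prog >= min_typed:
        seg = test_segregation(prog, _MODELS_FOR_DISCOVERY_HET,
                               alpha=alpha, min_typed=min_typed)
        if seg.best_model in ("ABxAA", "ABxBB", "ABxAB"):
            if germ_has_null:
                # segregation looks clean but germplasm shows a null-
                # homozygote cluster: null allele elsewhere in the pool
                return LocusClassification(
                    locus_id, "C3", seg.best_model, seg.best_p, call_rate,
                    note="null homozygotes observed in germplasm")
            return LocusClassification(locus_id, "C2", seg.best_model,
                                       seg.best_p, call_rate)
        if seg.best_model in NULL_MODELS:
            return LocusClassification(locus_id, "C3", seg.best_model,
                                       seg.best_p, call_rate)
        return LocusClassification(
            locus_id, "unassigned", "none", 0.0, call_rate,
            note="heterozygous discovery genotype but no segregation "
                 "model fits")

    # discovery looks homozygous: 00-segregating progeny exposes a
    # null heterozygote in the discovery genotype (00 x 0A and kin)
    if disc in (AA, BB) and n_typed_prog >= min_typed \
            and (prog == NULL2).any():
        models = (["A0x00", "A0xA0", "A0xB0"] if disc == AA
                  else ["B0x00", "B0xB0", "A0xB0"])
        seg = test_segregation(prog, models, alpha=alpha,
                               min_typed=min_typed)
        if seg.best_model != "none":
            return LocusClassification(locus_id, "C4", seg.best_model,
                                       seg.best_p, call_rate)
        return LocusClassification(
            locus_id, "unassigned", "none", 0.0, call_rate,
            note="00 progeny classes not fitting a discovery null-het "
                 "model")

    # no informative segregation: germplasm-level polymorphism
    has_A = np.isin(germ_typed, (AA, AB)).any()
    has_B = np.isin(germ_typed, (AB, BB)).any()
    has_null2 = germ_has_null
    if has_A and has_B:
        return LocusClassification(locus_id, "C5", call_rate=call_rate)
    if has_null2 and (has_A or has_B):
        return LocusClassification(locus_id, "C6", call_rate=call_rate)
    if has_null2 and not (has_A or has_B):
        return LocusClassification(locus_id, "C8", call_rate=call_rate,
                                   note="only null homozygotes observed")
    return LocusClassification(locus_id, "C8", call_rate=call_rate)


def classify_all(gm: GenotypeMatrix, scheme: PopulationScheme,
                 discovery_accession: str,
                 haploid_control: str | None = None,
                 call_rate_threshold: float = 0.8,
                 alpha: float = 0.01,
                 min_typed: int = 10) -> list[LocusClassification]:
    return [classify_locus(gm, l, scheme, discovery_accession,
                           haploid_control, call_rate_threshold, alpha,
                           min_typed)
            for l in gm.locus_ids]


def select_valid(classifications: list[LocusClassification],
                 gm: GenotypeMatrix,
                 max_missing: float = 0.05,
                 sources: dict[str, str] | None = None
                 ) -> list[MarkerRecord]:
    """Assign valid-set membership: WONA = C2+C5 and WNA = C3+C4+C6,
    each restricted to loci under the missing-data ceiling; everything
    else is excluded."""
    miss = dict(zip(gm.locus_ids, gm.missing_fraction()))
    out = []
    for c in classifications:
        if miss[c.locus_id] <= max_missing:
            if c.category in ("C2", "C5"):
                vs = "WONA"
            elif c.category in ("C3", "C4", "C6"):
                vs = "WNA"
            else:
                vs = "excluded"
        else:
            vs = "excluded"
        out.append(MarkerRecord(
            locus_id=c.locus_id,
            source=(sources or {}).get(c.locus_id, "BES"),
            category=c.category, valid_set=vs,
            diagnostics={"best_model": c.best_model, "p": c.p_value,
                         "call_rate": c.call_rate, "note": c.note}))
    return out
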