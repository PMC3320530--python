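"""Trio parentage scoring by Mendelian-compatibility counting.

For a putative hybrid and a candidate parent pair, each locus typed in
all three accessions is checked two ways:

* genotype-incompatible — no gamete pair, one allele drawn from each
  parent's observable genotype, reproduces the hybrid's observable
  genotype;
* orphan-allele — the hybrid carries an allele observed in neither
  parent.

Orphan-allele loci are always genotype-incompatible, so the orphan
count is the lenient, null-robust counter: null-aware mode treats every
homozygous parental call ``XX`` as possibly ``X/null``, letting an
apparently homozygous parent transmit a null allele, which can explain
a hybrid that looks homozygous for the other parent's allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from citrus_snp.genotype_io import (
    GenotypeMatrix, AA, AB, BB, NULL2, MISSING, observable_codes,
)

_ALLELES = {AA: ("A", "A"), AB: ("A", "B"), BB: ("B", "B"),
            NULL2: ("0", "0")}


def _observable_state(a1: str, a2: str) -> int:
    pair = frozenset((a1, a2))
    if pair == {"0"}:
        return NULL2
    if "0" in pair:
        (x,) = pair - {"0"}
        return AA if x == "A" else BB
    if pair == {"A"}:
        return AA
    if pair == {"B"}:
        return BB
    return AB


@lru_cache(maxsize=None)
def _compatible(hybrid: int, pa: int, pb: int, null_aware: bool) -> bool:
    def gametes(code: int) -> set:
        al = set(_ALLELES[code])
        if null_aware and len(al) == 1 and al != {"0"}:
            al = al | {"0"}
        return al
    return any(_observable_state(x, y) == hybrid
               for x in gametes(pa) for y in gametes(pb))


@lru_cache(maxsize=None)
def _orphan(hybrid: int, pa: int, pb: int, null_aware: bool) -> bool:
    present = set(_ALLELES[pa]) | set(_ALLELES[pb])
    if null_aware:
        for code in (pa, pb):
            if len(set(_ALLELES[code])) == 1 and _ALLELES[code][0] != "0":
                present.add("0")
    return any(a not in present for a in set(_ALLELES[hybrid]))


@dataclass
class ParentageReport:
    hybrid: str
    parent_a: str
    parent_b: str
    n_loci_tested: int
    n_genotype_incompatible: int
    n_orphan_allele: int
    percent_agreement: float
    null_aware: bool

    def __post_init__(self) -> None:
        assert self.n_orphan_allele <= self.n_genotype_incompatible


def trio_score(gm: GenotypeMatrix, hybrid: str, parent_a: str,
               parent_b: str, loci: list[str] | None = None,
               null_aware: bool = False) -> ParentageReport:
    """Score one trio over the locus set; loci missing in any member of
    the trio are dropped from the denominator.  Symmetric in parent
    order.  Scoring the hybrid against itself is allowed (it is always
    fully compatible) but almost certainly a caller mistake."""
    sub = gm.subset(loci=loci) if loci is not None else gm
    obs = observable_codes(sub.calls)
    h = obs[sub.acc_idx(hybrid)]
    a = obs[sub.acc_idx(parent_a)]
    b = obs[sub.acc_idx(parent_b)]
    ok = (h != MISSING) & (a != MISSING) & (b != MISSING)
    n_inc = n_orp = 0
    for hj, aj, bj in zip(h[ok], a[ok], b[ok]):
        if not _compatible(int(hj), int(aj), int(bj), null_aware):
            n_inc += 1
            if _orphan(int(hj), int(aj), int(bj), null_aware):
                n_orp += 1
    n = int(ok.sum())
    pct = 100.0 * (1.0 - n_inc / n) if n else float("nan")
    return ParentageReport(hybrid, parent_a, parent_b, n, n_inc, n_orp,
                           pct, null_aware)


def rank_hypotheses(gm: GenotypeMatrix, hybrid: str,
                    candidate_pairs: list[tuple[str, str]],
                    loci: list[str] | None = None,
                    null_aware: bool = False) -> list[ParentageReport]:
    """Score every candidate parent pair and sort by ascending
    genotype-incompatible count, then ascending orphan count, then
    lexically on the pair names."""
    if not candidate_pairs:
        raise ValueError("no candidate parent pairs")
    reports = [trio_score(gm, hybrid, pa, pb, loci, null_aware)
               for pa, pb in candidate_pairs]
    reports.sort(key=lambda r: (r.n_genotype_incompatible,
                                r.n_orphan_allele,
                                r.parent_a, r.parent_b))
    return reports
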