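"""Species × species mappable-loci matrices for comparative mapping.

A locus is mappable within a species when it segregates there: at least
two observed genotype states among the species' accessions (with-null
sets additionally count the presence/absence contrast between ``00``
and called states).  For a single named accession — e.g. the discovery
genotype — mappable means heterozygous, the loci that would segregate
in any cross with it.  Off-diagonal entries count loci mappable in both
species, the substrate of shared-marker comparative maps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from citrus_snp.genotype_io import (
    GenotypeMatrix, PopulationScheme, AA, AB, BB, NULL2, MISSING,
    observable_codes,
)


def mappable_loci(gm: GenotypeMatrix, scheme: PopulationScheme,
                  species: str, loci: list[str] | None = None,
                  include_null: bool = False) -> list[str]:
    """Loci mappable within `species` (a scheme group name, or a single
    accession id, in which case heterozygous loci are returned)."""
    sub = gm.subset(loci=loci) if loci is not None else gm
    obs = observable_codes(sub.calls)
    if species in scheme.groups:
        members = [a for a in scheme.groups[species]
                   if a in sub.accession_ids]
        if not members:
            raise ValueError(f"group {species} has no typed accessions")
        rows = obs[[sub.acc_idx(a) for a in members]]
        keep = []
        for j, lid in enumerate(sub.locus_ids):
            col = rows[:, j]
            states = {int(c) for c in col if c != MISSING}
            if not include_null:
                states -= {NULL2}
            if len(states) >= 2 or AB in states:
                keep.append(lid)
        return keep
    if species in sub.accession_ids:
        row = obs[sub.acc_idx(species)]
        return [lid for lid, c in zip(sub.locus_ids, row) if c == AB]
    raise ValueError(f"unknown species or accession {species!r}")


def mappability_matrix(gm: GenotypeMatrix, scheme: PopulationScheme,
                       wona_loci: list[str], wna_loci: list[str],
                       species: list[str] | None = None
                       ) -> dict[str, pd.DataFrame]:
    """Two symmetric shared-mappability matrices (one per marker class)
    plus a combined matrix whose diagonal is the within-species total
    over both classes."""
    if species is None:
        species = list(scheme.groups)
    if len(species) < 2:
        raise ValueError("need >= 2 species")
    mats = {}
    sets: dict[str, dict[str, set]] = {}
    for label, loci, incl_null in (("WONA", wona_loci, False),
                                   ("WNA", wna_loci, True)):
        sets[label] = {s: set(mappable_loci(gm, scheme, s, loci, incl_null))
                       for s in species}
        m = np.zeros((len(species), len(species)), dtype=int)
        for i, s in enumerate(species):
            for j, t in enumerate(species):
                m[i, j] = len(sets[label][s] & sets[label][t])
        mats[label] = pd.DataFrame(m, index=species, columns=species)
    mats["combined"] = mats["WONA"] + mats["WNA"]
    return mats
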