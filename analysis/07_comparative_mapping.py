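#!/usr/bin/env python
"""Comparative-mapping potential: species × species matrices of loci
segregating within each taxon (diagonal) and within both members of a
pair (off-diagonal), separately for the no-null and null-allele marker
classes.
"""

from pathlib import Path

import pandas as pd

from citrus_snp.genotype_io import read_genotype_table, PopulationScheme
from citrus_snp.comparative_mapping import mappability_matrix

RES = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    gm = read_genotype_table(RES / "sim" / "genotypes.tsv")
    sch = PopulationScheme.from_json(RES / "sim" / "scheme.json")
    rep = pd.read_csv(RES / "markers.tsv", sep="\t")
    wona = rep.loc[rep.valid_set == "WONA", "locus"].tolist()
    wna = rep.loc[rep.valid_set == "WNA", "locus"].tolist()

    mats = mappability_matrix(gm, sch, wona, wna)
    for label, m in mats.items():
        m.to_csv(RES / f"mappability_{label.lower()}.tsv", sep="\t")
    comb = mats["combined"]
    diag = pd.Series({s: comb.loc[s, s] for s in comb.index})
    print("within-species mappable loci (WONA+WNA):")
    for s, v in diag.sort_values(ascending=False).items():
        print(f"  {s:20s} {v}")
    wona_m = mats["WONA"]
    best, best_v = None, -1
    for i, s in enumerate(wona_m.index):
        for t in wona_m.columns[i + 1:]:
            if wona_m.loc[s, t] > best_v:
                best, best_v = (s, t), int(wona_m.loc[s, t])
    print(f"largest shared WONA pair: {best[0]} / {best[1]} ({best_v})")


if __name__ == "__main__":
    main()
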