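#!/usr/bin/env python
"""Diversity and F-statistics.

Per-taxon summaries (Ho, He, F, multilocus genotypes, and for the
null-allele set GD and the null-homozygote frequency), Weir-Cockerham
F-statistics over the three basic taxa, and the ascertainment contrast:
loci heterozygous in the discovery genotype (CHet) versus homozygous in
it (CHom).
"""

from pathlib import Path

import pandas as pd

from citrus_snp.genotype_io import read_genotype_table, PopulationScheme
from citrus_snp.diversity_stats import (group_summary, summary_frame,
                                        weir_cockerham)
from citrus_snp.synthetic_data import ascertain_markers

RES = Path(__file__).resolve().parents[1] / "results"
BASIC = ["reticulata_like", "maxima_like", "medica_like"]


def main() -> None:
    gm = read_genotype_table(RES / "sim" / "genotypes.tsv")
    sch = PopulationScheme.from_json(RES / "sim" / "scheme.json")
    rep = pd.read_csv(RES / "markers.tsv", sep="\t")
    wona = rep.loc[rep.valid_set == "WONA", "locus"].tolist()
    wna = rep.loc[rep.valid_set == "WNA", "locus"].tolist()

    t_wona = summary_frame(group_summary(gm, sch, wona))
    t_wona.to_csv(RES / "diversity_wona.tsv", sep="\t")
    print(f"WONA ({len(wona)} loci), all-sample Ho "
          f"{t_wona.loc['All samples', 'ho']:.3f}, He "
          f"{t_wona.loc['All samples', 'he']:.3f}")

    if wna:
        t_wna = summary_frame(group_summary(gm, sch, wna, null_aware=True))
        t_wna.to_csv(RES / "diversity_wna.tsv", sep="\t")
        nh = t_wna["null_homozygote_freq"].drop("All samples")
        print(f"WNA ({len(wna)} loci): null-homozygote frequency "
              f"highest in {nh.idxmax()} ({nh.max():.2f}), lowest in "
              f"{nh.idxmin()} ({nh.min():.2f})")

    rows = []
    chet = set(ascertain_markers(gm, "clementine_like", "CHet"))
    chom = set(ascertain_markers(gm, "clementine_like", "CHom"))
    for label, loci in (("all WONA", wona),
                        ("CHet", [l for l in wona if l in chet]),
                        ("CHom", [l for l in wona if l in chom])):
        fs = weir_cockerham(gm, sch, loci=loci, groups=BASIC)
        he_disc = group_summary(gm, sch, loci)["reticulata_like"].he
        rows.append({"loci": label, "n": fs.n_loci,
                     "fis": fs.fis, "fit": fs.fit, "fst": fs.fst,
                     "fst_se": fs.fst_se, "he_discovery_taxon": he_disc})
        print(f"{label:9s}: Fst {fs.fst:.3f} ± {fs.fst_se:.3f}, "
              f"He(discovery taxon) {he_disc:.3f}  (n={fs.n_loci})")
    pd.DataFrame(rows).to_csv(RES / "fstats.tsv", sep="\t", index=False)
    print("-> one-genotype ascertainment inflates within-taxon He and "
          "deflates between-taxa Fst for CHet vs CHom loci")


if __name__ == "__main__":
    main()
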