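"""End-to-end orchestration: simulate -> classify -> (diversity, tree,
pca, ld, parentage, mapmatrix), driven by one configuration mapping,
with a run manifest recording the seed, per-stage outputs and their
SHA-256 digests.  All randomness flows from one root seed through named
substreams, so a rerun with the same config and seed reproduces every
output digest byte-for-byte (timestamps live only in the manifest)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
import hashlib
import json

import numpy as np
import pandas as pd

from citrus_snp import synthetic_data as sd
from citrus_snp import marker_classification as mc
from citrus_snp import diversity_stats as dv
from citrus_snp import distance_ordination as do
from citrus_snp import linkage_disequilibrium as ld
from citrus_snp import parentage as pg
from citrus_snp import comparative_mapping as cm
from citrus_snp.genotype_io import write_genotype_table, summarize_selection

ALL_STAGES = ("simulate", "classify", "diversity", "tree", "pca", "ld",
              "parentage", "mapmatrix")


def stage_seed(root_seed: int, stage: str) -> int:
    """Named substream: stable 31-bit seed derived from the root seed."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class StageRecord:
    name: str
    outputs: dict[str, str]      # filename -> sha256
    started: str
    finished: str


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    stages: list[StageRecord] = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config_digest": self.config_digest, "seed": self.seed,
             "stages": [asdict(s) for s in self.stages]}, indent=1))


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def build_sim_config(section: dict, seed: int) -> sd.SimulationConfig:
    kw = dict(section or {})
    if "taxa" in kw:
        kw["taxa"] = [sd.TaxonSpec(*t) for t in kw["taxa"]]
    if "hybrids" in kw:
        kw["hybrids"] = [sd.HybridSpec(h[0], tuple(h[1]), *h[2:])
                         for h in kw["hybrids"]]
    if "cross" in kw:
        kw["cross"] = tuple(kw["cross"])
    kw["seed"] = seed
    return sd.SimulationConfig(**kw)


def run_all(config: dict, out_dir, stages: list[str] | None = None
            ) -> RunManifest:
    """Run the requested stages (default: all) into `out_dir` and write
    ``manifest.json`` last.  A stage failure aborts after writing the
    partial manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 42))
    wanted = list(stages) if stages else list(ALL_STAGES)
    unknown = set(wanted) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest = RunManifest(
        config_digest=hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest(),
        seed=seed)

    state: dict = {}

    def record(name: str, started: str, files: list[Path]) -> None:
        manifest.stages.append(StageRecord(
            name=name, outputs={f.name: _sha256(f) for f in files},
            started=started, finished=_now()))

    try:
        _run_stages(config, out, seed, wanted, state, record)
    finally:
        manifest.to_json(out / "manifest.json")
    return manifest


def _ensure_dataset(config, out, seed, state):
    if "dataset" not in state:
        cfg = build_sim_config(config.get("simulate"),
                               stage_seed(seed, "simulate"))
        state["dataset"] = sd.simulate_dataset(cfg)
    return state["dataset"]


def _ensure_markers(config, out, seed, state):
    if "markers" not in state:
        ds = _ensure_dataset(config, out, seed, state)
        sec = config.get("classify") or {}
        cls = mc.classify_all(
            ds.genotypes, ds.scheme, ds.config.discovery_accession,
            haploid_control=(ds.config.haploid_control_name
                             if ds.config.include_haploid_control else None),
            call_rate_threshold=sec.get("call_rate_threshold", 0.8),
            alpha=sec.get("alpha", 0.01))
        markers = mc.select_valid(cls, ds.genotypes,
                                  max_missing=sec.get("max_missing", 0.05))
        state["classifications"] = cls
        state["markers"] = markers
        state["wona"] = [m.locus_id for m in markers
                         if m.valid_set == "WONA"]
        state["wna"] = [m.locus_id for m in markers if m.valid_set == "WNA"]
    return state["markers"]


def _run_stages(config, out, seed, wanted, state, record):
    if "simulate" in wanted:
        t0 = _now()
        ds = _ensure_dataset(config, out, seed, state)
        write_genotype_table(ds.genotypes, out / "genotypes.tsv")
        write_genotype_table(ds.truth_genotypes, out / "genotypes_truth.tsv")
        sd.truth_to_json(ds, out / "truth.json")
        ds.scheme.to_json(out / "scheme.json")
        record("simulate", t0, [out / "genotypes.tsv",
                                out / "genotypes_truth.tsv",
                                out / "truth.json", out / "scheme.json"])

    if "classify" in wanted:
        t0 = _now()
        markers = _ensure_markers(config, out, seed, state)
        rows = []
        for c, m in zip(state["classifications"], markers):
            rows.append({"locus": m.locus_id, "category": m.category,
                         "valid_set": m.valid_set,
                         "best_model": c.best_model, "p": c.p_value,
                         "call_rate": c.call_rate, "note": c.note})
        pd.DataFrame(rows).to_csv(out / "markers.tsv", sep="\t",
                                  index=False)
        s = summarize_selection(markers)
        (out / "selection_summary.json").write_text(
            json.dumps(asdict(s), indent=1))
        record("classify", t0, [out / "markers.tsv",
                                out / "selection_summary.json"])

    if "diversity" in wanted:
        t0 = _now()
        ds = _ensure_dataset(config, out, seed, state)
        _ensure_markers(config, out, seed, state)
        files = []
        for label, loci, null_aware in (("wona", state["wona"], False),
                                        ("wna", state["wna"], True)):
            if not loci:
                continue
            summ = dv.group_summary(ds.genotypes, ds.scheme, loci,
                                    null_aware=null_aware)
            f = out / f"diversity_{label}.tsv"
            dv.summary_frame(summ).to_csv(f, sep="\t")
            files.append(f)
        sec = config.get("diversity") or {}
        fs_groups = sec.get("fstat_groups")
        if fs_groups is None:
            fs_groups = [g for g in ds.scheme.groups
                         if len([a for a in ds.scheme.groups[g]
                                 if ds.scheme.roles.get(a) == "germplasm"])
                         >= 2][:3]
        if state["wona"] and len(fs_groups) >= 2:
            fs = dv.weir_cockerham(ds.genotypes, ds.scheme,
                                   loci=state["wona"], groups=fs_groups)
            pd.DataFrame([{"fis": fs.fis, "fit": fs.fit, "fst": fs.fst,
                           "fis_se": fs.fis_se, "fit_se": fs.fit_se,
                           "fst_se": fs.fst_se, "n_loci": fs.n_loci}]
                         ).to_csv(out / "fstats.tsv", sep="\t", index=False)
            files.append(out / "fstats.tsv")
        record("diversity", t0, files)

    if "tree" in wanted:
        t0 = _now()
        ds = _ensure_dataset(config, out, seed, state)
        _ensure_markers(config, out, seed, state)
        sec = config.get("tree") or {}
        germ = ds.scheme.germplasm
        germ = [a for a in germ if a != ds.config.haploid_control_name]
        tree = do.bootstrap_support(
            ds.genotypes, loci=state["wona"] or None, accessions=germ,
            n_reps=sec.get("bootstrap", 200),
            seed=stage_seed(seed, "tree"))
        (out / "nj_wona.nwk").write_text(tree.newick())
        record("tree", t0, [out / "nj_wona.nwk"])

    if "pca" in wanted:
        t0 = _now()
        ds = _ensure_dataset(config, out, seed, state)
        _ensure_markers(config, out, seed, state)
        sec = config.get("pca") or {}
        germ = [a for a in ds.scheme.germplasm
                if a != ds.config.haploid_control_name]
        active_groups = sec.get("active_groups")
        if active_groups:
            active = [a for g in active_groups for a in ds.scheme.groups[g]
                      if a in germ]
        else:
            active = germ
        res = do.pca(ds.genotypes, loci=state["wona"] or None,
                     active=active,
                     supplementary=[a for a in germ if a not in set(active)])
        res.coordinates.to_csv(out / "pca_coords.tsv", sep="\t")
        record("pca", t0, [out / "pca_coords.tsv"])

    if "ld" in wanted:
        t0 = _now()
        ds = _ensure_dataset(config, out, seed, state)
        _ensure_markers(config, out, seed, state)
        sec = config.get("ld") or {}
        loci = state["wona"][:sec.get("max_loci", 150)]
        rows = []
        germ = [a for a in ds.scheme.germplasm
                if a != ds.config.haploid_control_name]
        prog = ds.scheme.accessions_with_role("progeny")
        for panel, accs in (("germplasm", germ), ("progeny", prog)):
            res = ld.ld_matrix(ds.genotypes, loci=loci, accessions=accs)
            if res.empty:
                continue
            s = ld.ld_summary(res, r2_threshold=sec.get("threshold", 0.2))
            rows.append({"panel": panel, "n_pairs": s.n_pairs,
                         "mean_r2": s.mean_r2,
                         "pct_above": s.percent_above_threshold})
        pd.DataFrame(rows).to_csv(out / "ld_summary.tsv", sep="\t",
                                  index=False)
        record("ld", t0, [out / "ld_summary.tsv"])

    if "parentage" in wanted:
        t0 = _now()
        ds = _ensure_dataset(config, out, seed, state)
        _ensure_markers(config, out, seed, state)
        sec = config.get("parentage") or {}
        hybrid = sec.get("hybrid", "sweet_orange_like_1")
        pairs = [tuple(p) for p in sec.get("pairs", [])]
        if not pairs:
            germ = [a for a in ds.scheme.germplasm
                    if a != ds.config.haploid_control_name and a != hybrid]
            pairs = [(germ[i], germ[j])
                     for i in range(0, min(len(germ), 10), 2)
                     for j in range(1, min(len(germ), 10), 2) if i != j]
        reports = pg.rank_hypotheses(ds.genotypes, hybrid, pairs,
                                     loci=state["wona"] or None,
                                     null_aware=sec.get("null_aware", False))
        pd.DataFrame([asdict(r) for r in reports]).to_csv(
            out / "parentage.tsv", sep="\t", index=False)
        record("parentage", t0, [out / "parentage.tsv"])

    if "mapmatrix" in wanted:
        t0 = _now()
        ds = _ensure_dataset(config, out, seed, state)
        _ensure_markers(config, out, seed, state)
        mats = cm.mappability_matrix(ds.genotypes, ds.scheme,
                                     state["wona"], state["wna"])
        files = []
        for label, m in mats.items():
            f = out / f"mappability_{label.lower()}.tsv"
            m.to_csv(f, sep="\t")
            files.append(f)
        record("mapmatrix", t0, files)
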