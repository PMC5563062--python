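"""End-to-end orchestration: simulate -> map -> abundance -> sololtr ->
conserve -> date -> profiles.

Each stage is a function taking (config, outdir); stages communicate
only through files in the output directory (FASTA for sequences, TSV for
tables, Newick for trees), so any stage can be rerun in isolation on
existing inputs.  A run manifest records versions, seed and parameters;
rerunning with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import sys
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import AbundanceTable
from .clustering import cluster_species, group_repeat_clusters
from .dating import (StringencyCounts, burst_histogram, conservation_index,
                     harvest_rt_reads, pairwise_k2p)
from .io import read_sequences, read_tsv, write_sequences, write_tsv
from .mapping import compute_coverage, map_reads
from .simulate import (FamilyModel, SpeciesModel, build_genome, random_master,
                       reads_for_ploidy, sample_reads)
from .solo_ltr import (ElementPartition, ltr_internal_ratio, ratios_to_frame,
                       summarize_by_species)

STAGES = ("simulate", "map", "abundance", "sololtr", "conserve", "date", "profiles")

MYA = 1e6


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


def _seed_for(config: dict, stage: str, item: str = "") -> int:
    """Deterministic per-stage/per-item child seed below 2**31."""
    root = int(config.get("seed", 0))
    ss = np.random.SeedSequence([root, STAGES.index(stage), zlib.crc32(item.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _species_ids(config: dict) -> list[str]:
    return [sp["id"] for sp in config["simulation"]["species"]]


# ---------------------------------------------------------------- simulate


def stage_simulate(config: dict, outdir: Path) -> None:
    sim = config["simulation"]
    rate = float(config.get("substitution_rate", 2e-8))
    kappa = float(config.get("kappa", 2.0))
    read_length = int(config.get("read_length", 90))
    error_rate = float(config.get("error_rate", 0.001))
    masters = {}
    ann_rows = []
    part_rows = []
    for i, fam in enumerate(sim["families"]):
        m = random_master(
            fam["id"], fam.get("superfamily", "unknown"), fam.get("lineage", "unknown"),
            fam["ltr_length"], fam["internal_length"],
            seed=_seed_for(config, "simulate", f"master:{fam['id']}"),
        )
        masters[m.id] = m
        ann_rows.append((m.id, m.superfamily, m.lineage, fam.get("sublineage", "")))
        part_rows.append((m.id, len(m.ltr_seq), len(m.ltr_seq) + len(m.internal_seq),
                          m.superfamily, m.lineage))
    write_sequences([(m.id, m.sequence) for m in masters.values()],
                    outdir / "references.fasta")
    write_sequences([(m.id, m.ltr_seq + m.internal_seq) for m in masters.values()],
                    outdir / "partition_references.fasta")
    write_sequences([(m.id, m.rt_seq) for m in masters.values()],
                    outdir / "rt_references.fasta")
    write_tsv(pd.DataFrame(ann_rows, columns=["cluster_id", "superfamily", "lineage",
                                              "sublineage"]),
              outdir / "annotation.tsv", "simulate", index=False)
    write_tsv(pd.DataFrame(part_rows, columns=["element_id", "ltr_end", "total_length",
                                               "superfamily", "lineage"]),
              outdir / "partitions.tsv", "simulate", index=False)
    reads_per_diploid = int(sim.get("reads_per_diploid", 1_000_000))
    totals = {}
    for sp in sim["species"]:
        fams = tuple(
            FamilyModel(f["master"], int(f.get("intact", 0)), int(f.get("solo", 0)),
                        float(f.get("age_mya", 0.0)) * MYA)
            for f in sp["families"]
        )
        model = SpeciesModel(sp["id"], int(sp.get("ploidy", 2)), fams,
                             int(sp["background_length"]), rate, kappa)
        genome = build_genome(model, masters,
                              seed=_seed_for(config, "simulate", f"genome:{sp['id']}"))
        n_reads = sp.get("n_reads") or reads_for_ploidy(model.ploidy, reads_per_diploid)
        reads = sample_reads(genome, int(n_reads), read_length, error_rate,
                             seed=_seed_for(config, "simulate", f"reads:{sp['id']}"))
        totals[sp["id"]] = len(reads)
        write_sequences(reads, outdir / f"reads_{sp['id']}.fasta")
        truth = genome.truth.copy()
        truth.insert(0, "species_id", sp["id"])
        truth = truth.rename(columns={"master_id": "family", "start": "locus_start",
                                      "end": "locus_end"})
        write_tsv(truth, outdir / f"truth_{sp['id']}.tsv", "simulate", index=False)
    write_tsv(pd.Series(totals, name="total_reads").rename_axis("species_id").to_frame(),
              outdir / "read_totals.tsv", "simulate")


# ---------------------------------------------------------------- mapping


def _load_refs(outdir: Path, name: str) -> dict[str, str]:
    return {r.id: r.seq for r in read_sequences(outdir / name)}


def stage_map(config: dict, outdir: Path) -> None:
    tier = config.get("stringency", "high")
    refs = _load_refs(outdir, "references.fasta")
    for sp in _species_ids(config):
        reads = read_sequences(outdir / f"reads_{sp}.fasta")
        result = map_reads(reads, refs, tier, seed=_seed_for(config, "map", sp))
        write_tsv(result.table, outdir / f"mapping_{sp}.tsv", "map",
                  {"tier": tier, "species": sp, "n_mapped": result.n_mapped,
                   "n_unmapped": result.n_unmapped}, index=False)


# ---------------------------------------------------------------- abundance


def stage_abundance(config: dict, outdir: Path) -> None:
    annotation = read_tsv(outdir / "annotation.tsv").set_index("cluster_id")
    totals = read_tsv(outdir / "read_totals.tsv").set_index("species_id")["total_reads"]
    counts = {}
    for sp in _species_ids(config):
        table = read_tsv(outdir / f"mapping_{sp}.tsv")
        counts[sp] = table["ref_id"].value_counts()
    counts_df = (pd.DataFrame(counts).T.reindex(columns=sorted(annotation.index))
                 .fillna(0).astype(int))
    table = AbundanceTable(counts_df, totals, annotation)
    write_tsv(table.gp, outdir / "abundance_gp.tsv", "abundance",
              {"denominator": "total reads per species"})
    write_tsv(table.lineage_gp(), outdir / "abundance_lineage_gp.tsv", "abundance")
    sf = table.superfamily_gp()
    sf["repetitive_fraction"] = table.repetitive_fraction()
    if "Gypsy" in sf.columns and "Copia" in sf.columns:
        sf["gypsy_copia_ratio"] = table.gypsy_copia_ratios()
    write_tsv(sf, outdir / "abundance_superfamily.tsv", "abundance")


# ---------------------------------------------------------------- solo-LTR


def stage_sololtr(config: dict, outdir: Path) -> None:
    tier = config.get("stringency", "high")
    refs = _load_refs(outdir, "partition_references.fasta")
    parts = read_tsv(outdir / "partitions.tsv")
    partitions = {
        row.element_id: ElementPartition(row.element_id, int(row.ltr_end),
                                         int(row.total_length))
        for row in parts.itertuples()
    }
    all_ratios = []
    for sp in _species_ids(config):
        reads = read_sequences(outdir / f"reads_{sp}.fasta")
        mapping = map_reads(reads, refs, tier, seed=_seed_for(config, "sololtr", sp))
        for eid, partition in partitions.items():
            cov = compute_coverage(mapping, eid)
            all_ratios.append(ltr_internal_ratio(cov, partition, species_id=sp))
    df = ratios_to_frame(all_ratios)
    write_tsv(df, outdir / "sololtr_ratios.tsv", "sololtr", {"tier": tier}, index=False)
    write_tsv(summarize_by_species(df), outdir / "sololtr_summary.tsv", "sololtr")


# ---------------------------------------------------------------- conservation


def stage_conserve(config: dict, outdir: Path) -> None:
    rt_refs = _load_refs(outdir, "rt_references.fasta")
    annotation = read_tsv(outdir / "annotation.tsv").set_index("cluster_id")
    rows = []
    for sp in _species_ids(config):
        reads = read_sequences(outdir / f"reads_{sp}.fasta")
        per_tier = {}
        for tier in ("high", "medium", "low"):
            mapping = map_reads(reads, rt_refs, tier,
                                seed=_seed_for(config, "conserve", f"{sp}:{tier}"))
            per_tier[tier] = mapping.table.dropna(subset=["ref_id"])
        for ref_id in sorted(rt_refs):
            lineage = annotation.at[ref_id, "lineage"]
            n = {t: int((per_tier[t]["ref_id"] == ref_id).sum())
                 for t in ("high", "medium", "low")}
            counts = StringencyCounts(sp, lineage, n["high"], n["medium"], n["low"])
            ci = conservation_index(counts)
            rows.append((sp, ref_id, lineage, n["high"], n["medium"], n["low"],
                         ci.value, ci.defined))
    write_tsv(pd.DataFrame(rows, columns=["species_id", "family", "lineage", "n_high",
                                          "n_medium", "n_low", "conservation_index",
                                          "defined"]),
              outdir / "conservation.tsv", "conserve", index=False)


# ---------------------------------------------------------------- dating


def stage_date(config: dict, outdir: Path) -> None:
    rate = float(config.get("substitution_rate", 2e-8))
    bin_width = float(config.get("bin_width_mya", 0.5))
    min_overlap = int(config.get("min_overlap", 30))
    cap = int(config.get("rt_read_cap", 500))
    tier = config.get("dating_stringency", "medium")
    rt_refs = _load_refs(outdir, "rt_references.fasta")
    target = config.get("dating_family") or sorted(rt_refs)[0]
    hist_rows = []
    dist_frames = []
    for sp in _species_ids(config):
        reads = read_sequences(outdir / f"reads_{sp}.fasta")
        harvest = harvest_rt_reads(reads, rt_refs[target], tier, species_id=sp,
                                   ref_id=target, cap=cap,
                                   seed=_seed_for(config, "date", sp))
        if harvest.profiles.shape[0] < 2:
            print(f"[date] {sp}: fewer than 2 RT reads harvested; skipped",
                  file=sys.stderr)
            continue
        dists = pairwise_k2p(harvest, min_overlap=min_overlap)
        tbl = dists.table.copy()
        tbl.insert(0, "species_id", sp)
        tbl["T_mya"] = tbl["K"] / (2.0 * rate) / MYA
        dist_frames.append(tbl)
        hist = burst_histogram(dists, rate, bin_width)
        for lo, hi, pct in zip(hist.edges[:-1], hist.edges[1:], hist.percent):
            hist_rows.append((sp, target, lo, hi, pct, hist.apex_mya))
    if dist_frames:
        write_tsv(pd.concat(dist_frames, ignore_index=True),
                  outdir / "rt_pairwise_distances.tsv", "date",
                  {"rate": rate, "family": target, "min_overlap": min_overlap},
                  index=False)
    write_tsv(pd.DataFrame(hist_rows, columns=["species_id", "family", "bin_low_mya",
                                               "bin_high_mya", "percent", "apex_mya"]),
              outdir / "burst_histogram.tsv", "date",
              {"rate": rate, "bin_width_mya": bin_width}, index=False)


# ---------------------------------------------------------------- profiles


def stage_profiles(config: dict, outdir: Path) -> None:
    gp = read_tsv(outdir / "abundance_gp.tsv", index_col=0)
    n_boot = int(config.get("n_bootstrap", 1000))
    if gp.shape[0] >= 3:
        tree = cluster_species(gp, n_boot=n_boot,
                               seed=_seed_for(config, "profiles", "species"))
        (outdir / "species_dendrogram.nwk").write_text(tree.to_newick() + "\n")
    else:
        print("[profiles] fewer than 3 species; dendrogram skipped", file=sys.stderr)
    groups = group_repeat_clusters(gp.T, cut_fraction=float(config.get("cut_fraction", 0.5)))
    write_tsv(groups.rename_axis("cluster_id"), outdir / "cluster_groups.tsv",
              "profiles", {"cut_fraction": config.get("cut_fraction", 0.5)})


# ---------------------------------------------------------------- driver

_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "map": stage_map,
    "abundance": stage_abundance,
    "sololtr": stage_sololtr,
    "conserve": stage_conserve,
    "date": stage_date,
    "profiles": stage_profiles,
}


def run_stage(name: str, config: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        _STAGE_FUNCS[name](config, outdir)
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: dict, outdir) -> Path:
    """Run all stages and write a manifest; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in STAGES:
        run_stage(name, config, outdir)
    manifest = {
        "package": "repeatome",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": int(config.get("seed", 0)),
        "stages": list(STAGES),
        "parameters": {k: v for k, v in config.items() if k != "simulation"},
        "species": _species_ids(config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
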