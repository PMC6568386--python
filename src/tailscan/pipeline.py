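"""Single-config orchestration of the full selection-signature analysis.

One declarative YAML config drives: QC -> (optional) MDS -> per-comparison
iES/Rsb scan and FST/chi2 corroboration -> shared candidate regions -> ROH
and ROH islands per group -> region/island overlap -> (optional) gene
annotation.  Every stage is also callable standalone through the library
API; output is a pure function of (inputs, config, seed).

Config layout (keys with defaults may be omitted)::

    input:
      ped: sim.ped          # or  simulate: {preset: sweep_scan, seed: 42}
      map: sim.map
      phased: true
      impute_missing: false
    groups:                 # optional pooled groups (label -> PED FIDs)
      thin_pool: [breedA, breedB]
    comparisons:            # fat-tail group first, one fat + one thin each
      - {name: "1", fat: pop1, thin: thin_pool}
    qc: {max_sample_missing: 0.10, min_snp_call_rate: 0.95, min_maf: 0.01}
    ies: {ehhs_cutoff: 0.05, max_gap_bp: 500000}
    regions: {threshold: 3.3, max_gap_bp: 200000, min_snps: 2,
              flank_bp: 200000, min_comparisons: 2, alpha: 0.05}
    roh: {min_length_bp: 1000000, max_het: 1, max_missing: 1, min_snps: 30,
          min_density_bp_per_snp: 100000, max_gap_bp: 1000000}
    islands: {quantile: 0.9999, merge_gap_bp: 1000000, min_island_snps: 3}
    mds: {k: 2}             # optional stage
    genes: genes.gff3       # optional (".bed" or ".gff3")
    out_dir: results
    seed: 1
"""

from __future__ import annotations

import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import tailscan
from tailscan import ehh_core, fst_chi2, popstructure, regions as regions_mod, roh as roh_mod
from tailscan.genotype_io import GenotypeDataset, QcParams, apply_qc, read_plink
from tailscan.rsb_scan import rsb_scan
from tailscan.simulate import SimParams, SweepSpec, simulate_two_pops

COORD_HEADER = "# coordinates: 1-based inclusive (bp)\n"


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and cause."""


def _log(msg: str) -> None:
    print(f"[tailscan] {msg}", file=sys.stderr)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _validate(cfg: dict) -> None:
    if "comparisons" not in cfg or not cfg["comparisons"]:
        raise ConfigError("config needs a non-empty 'comparisons' list")
    for comp in cfg["comparisons"]:
        if not {"name", "fat", "thin"} <= set(comp):
            raise ConfigError(f"comparison {comp!r} needs name, fat and thin")
    if "input" not in cfg:
        raise ConfigError("config needs an 'input' section")
    if "out_dir" not in cfg:
        raise ConfigError("config needs 'out_dir'")


def _resolve_group(cfg: dict, label: str) -> str | list[str]:
    pooled = (cfg.get("groups") or {}).get(label)
    return pooled if pooled is not None else label


def _write(df: pd.DataFrame, path: Path, written: list[Path] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER)
        df.to_csv(fh, sep="\t", index=False)
    if written is not None:
        written.append(path)


def _load_input(cfg: dict) -> GenotypeDataset:
    inp = cfg["input"]
    if "simulate" in inp:
        sim = dict(inp["simulate"])
        preset = sim.pop("preset", None)
        seed = sim.pop("seed", cfg.get("seed", 0))
        if preset == "sweep_scan":
            sim.setdefault("sweep", {"chrom": 1, "pos_bp": 50_000_000, "s": 0.2, "population": 1})
        sweep = sim.pop("sweep", None)
        params = SimParams(
            seed=seed, sweep=None if sweep is None else SweepSpec(**sweep), **sim
        )
        ds, _ = simulate_two_pops(params)
        return ds
    return read_plink(
        inp["ped"], inp["map"], phased=inp.get("phased", True), impute_missing=inp.get("impute_missing", False)
    )


def run_pipeline(cfg: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis; returns a dict of result objects and writes
    tab-separated tables plus a run log under ``out_dir``."""
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    _validate(cfg)
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    written: list[Path] = []
    stage = "input"
    try:
        ds = _load_input(cfg)
        _log(f"input: {ds.n_samples} samples x {ds.n_snps} SNPs")

        stage = "qc"
        qc_cfg = cfg.get("qc") or {}
        ds, report = apply_qc(ds, QcParams(**qc_cfg))
        report.to_tsv(out / "qc_report.tsv")
        _log(f"qc: retained {report.n_samples_retained} samples x {report.n_snps_retained} SNPs")

        results: dict = {"dataset": ds, "qc_report": report}

        if "mds" in cfg:
            stage = "mds"
            dm = popstructure.ibs_distance(ds)
            mds = popstructure.classical_mds(dm, int(cfg["mds"].get("k", 2)))
            coords = pd.DataFrame(
                mds.coords, columns=[f"C{i + 1}" for i in range(mds.coords.shape[1])]
            )
            coords.insert(0, "group", ds.groups)
            coords.insert(0, "sample", ds.sample_ids)
            _write(coords, out / "mds_coordinates.tsv", written)
            results["mds"] = mds

        reg_cfg = {
            "threshold": 3.3,
            "max_gap_bp": 200_000,
            "min_snps": 2,
            "flank_bp": 200_000,
            "min_comparisons": 2,
            "alpha": 0.05,
            **(cfg.get("regions") or {}),
        }
        ies_params = ehh_core.IesParams(**(cfg.get("ies") or {}))

        stage = "ies"
        units: dict[str, str | list[str]] = {}
        for comp in cfg["comparisons"]:
            for side in ("fat", "thin"):
                label = comp[side] if isinstance(comp[side], str) else "+".join(comp[side])
                units[label] = _resolve_group(cfg, comp[side]) if isinstance(comp[side], str) else comp[side]
        ies_tables = {}
        for label, group in units.items():
            hs = ehh_core.haplotype_set(ds, group)
            ies_tables[label] = ehh_core.ies_table(hs, ies_params)
            _log(f"ies: {label}: {int(ies_tables[label]['ies'].notna().sum())} SNPs computed")

        stage = "rsb"
        scans = {}
        diffs = {}
        cluster_lists = []
        for comp in cfg["comparisons"]:
            name = str(comp["name"])
            fat_label = comp["fat"] if isinstance(comp["fat"], str) else "+".join(comp["fat"])
            thin_label = comp["thin"] if isinstance(comp["thin"], str) else "+".join(comp["thin"])
            scan = rsb_scan(ies_tables[fat_label], ies_tables[thin_label], comparison=name)
            scans[name] = scan
            _write(scan, out / f"rsb_scan_{name}.tsv", written)
            diff = fst_chi2.diff_scan(ds, units[fat_label], units[thin_label])
            diffs[name] = diff
            _write(diff, out / f"fst_chi2_{name}.tsv", written)
            cluster_lists.append(
                regions_mod.significant_clusters(
                    scan,
                    threshold=reg_cfg["threshold"],
                    max_gap_bp=reg_cfg["max_gap_bp"],
                    min_snps=reg_cfg["min_snps"],
                    comparison=name,
                )
            )
        results["scans"] = scans
        results["diffs"] = diffs

        stage = "regions"
        shared = regions_mod.shared_regions(
            cluster_lists, flank_bp=reg_cfg["flank_bp"], min_comparisons=reg_cfg["min_comparisons"]
        )
        regions_mod.corroborate_chi2(shared, diffs, flank_bp=reg_cfg["flank_bp"], alpha=reg_cfg["alpha"])
        if cfg.get("genes"):
            gpath = str(cfg["genes"])
            genes = (
                regions_mod.read_bed(gpath) if gpath.endswith(".bed") else regions_mod.read_gff3(gpath)
            )
            regions_mod.annotate_genes(shared, genes)
        results["regions"] = shared
        _log(f"regions: {len(shared)} shared candidate regions")

        stage = "roh"
        roh_params = roh_mod.RohParams(**(cfg.get("roh") or {}))
        isl_cfg = {"quantile": 0.9999, "merge_gap_bp": 1_000_000, "min_island_snps": 3, **(cfg.get("islands") or {})}
        islands_by_group: dict[str, list] = {}
        seg_frames = []
        for label, group in units.items():
            segs = roh_mod.call_roh_group(ds, group, roh_params)
            frame = roh_mod.segments_to_frame(segs)
            frame.insert(0, "group", label)
            seg_frames.append(frame)
            lh = roh_mod.locus_homozygosity(segs, ds, group)
            try:
                islands_by_group[label] = roh_mod.roh_islands(
                    lh,
                    ds.snps,
                    quantile=isl_cfg["quantile"],
                    merge_gap_bp=isl_cfg["merge_gap_bp"],
                    min_island_snps=isl_cfg["min_island_snps"],
                )
            except ValueError:
                _log(f"roh: {label}: flat incidence, no islands")
                islands_by_group[label] = []
        _write(pd.concat(seg_frames, ignore_index=True), out / "roh_segments.tsv", written)
        island_rows = [
            (g, i.chrom, i.start_bp, i.end_bp, i.n_snps, i.threshold)
            for g, isls in islands_by_group.items()
            for i in isls
        ]
        _write(
            pd.DataFrame(
                island_rows, columns=["group", "chrom", "start_bp", "end_bp", "n_snps", "threshold"]
            ),
            out / "roh_islands.tsv",
        )
        results["islands"] = islands_by_group

        stage = "overlap"
        fat_labels = {
            (c["fat"] if isinstance(c["fat"], str) else "+".join(c["fat"])) for c in cfg["comparisons"]
        }
        overlap = regions_mod.overlap_islands(
            shared, {g: isls for g, isls in islands_by_group.items() if g in fat_labels}
        )
        results["overlap"] = overlap
        _write(regions_mod.regions_to_frame(shared), out / "candidate_regions.tsv", written)
        with open(out / "overlap_summary.tsv", "w") as fh:
            fh.write(COORD_HEADER)
            fh.write("n_overlapping_islands\t%d\n" % overlap.n_overlapping_islands)
            for region, isl in overlap.pairs:
                fh.write(
                    f"region\t{region.chrom}:{region.start_bp}-{region.end_bp}\t"
                    f"island\t{isl.chrom}:{isl.start_bp}-{isl.end_bp}\t{','.join(sorted(isl.groups))}\n"
                )

        with open(out / "run_log.txt", "w") as fh:
            fh.write(f"tailscan {tailscan.__version__}\n")
            fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
            fh.write(f"seed\t{cfg.get('seed', 'NA')}\n")
            fh.write(f"thresholds\t{reg_cfg}\n")
            fh.write(f"ies\t{ies_params}\n")
            fh.write(f"roh\t{roh_params}\n")
            fh.write(f"islands\t{isl_cfg}\n")
            fh.write(f"elapsed_s\t{time.time() - t0:.1f}\n")
        return results
    except ConfigError:
        raise
    except Exception as exc:
        for path in written:  # keep partial outputs, clearly marked
            try:
                path.rename(path.with_name(path.name + ".partial"))
            except OSError:
                pass
        raise StageError(f"stage '{stage}' failed: {exc}") from exc
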