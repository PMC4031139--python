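"""End-to-end orchestration: simulate -> detect -> classify -> profile ->
call -> linkers -> sites, from one config and one seed, with a
machine-readable JSON report.

The pipeline is deterministic: every stage's randomness derives from the
global seed, and the report records a content checksum for each file
written, so identical config + seed reproduce an identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from . import io as nbio
from .classify import CATEGORY_ORDER, classify_all, category_summary
from .detect import FdrError, call_dhs, cut_density, fdr_threshold, sample_random_tags
from .intervals import jaccard
from .linkers import (
    LinkerSample,
    compare_classes,
    dyad_spacing,
    strand_peak_linkers,
    summarize,
)
from .nucleosomes import call_nucleosomes, dyad_track, smooth_fft
from .profiles import anchor_set, oscillation_metrics, strand_profile
from .simulate import SimulationConfig, BarrierClassSpec, simulate, write_simulation
from .sites import analyze_sites

log = logging.getLogger("nucbarrier")

LINKER_CLASSES = ("intergenic", "genic", "proximal")


@dataclass
class PipelineConfig:
    outdir: str = "nucbarrier_run"
    seed: int = 0
    # simulation (study conditions); None -> package defaults
    simulation: Optional[SimulationConfig] = None
    # DHS detection; the toy-genome default bandwidth follows the
    # feature-length/6 heuristic for the simulated barrier scale
    # (~60-400 bp), see docs/methods.md
    bandwidth: float = 15.0
    fdr: float = 0.05
    fdr_conservative: float = 3.0
    n_random_datasets: int = 10
    merge_gap: int = 50
    min_len: int = 20
    # profiles
    flank: int = 1000
    bin: int = 20
    # nucleosome calling
    keep_frac: float = 0.02
    height_quantile: float = 0.75
    min_sep: int = 120
    max_phased_width: int = 150
    # linkers
    min_peak_sep: int = 100
    linker_window: int = 1000
    # sites
    site_flank: int = 50
    n_random_sites: Optional[int] = None
    # stage toggles
    stages: tuple = ("simulate", "detect", "classify", "profile", "call", "linkers", "sites")
    write_tracks: bool = False
    # optional external inputs; when set they must exist before any stage runs
    sites_bed: Optional[str] = None

    @classmethod
    def from_toml(cls, path: str, seed: Optional[int] = None) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim_raw = raw.pop("simulation", None)
        sim = None
        if sim_raw is not None:
            classes_raw = sim_raw.pop("classes", None)
            sim = SimulationConfig(**sim_raw)
            if classes_raw:
                sim.classes = {
                    name: BarrierClassSpec(**spec) for name, spec in classes_raw.items()
                }
        cfg = cls(simulation=sim, **raw)
        if seed is not None:
            cfg.seed = seed
        return cfg


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run the enabled stages in dependency order and return the report."""
    t0 = time.time()
    if config.sites_bed is not None and not os.path.exists(config.sites_bed):
        raise FileNotFoundError(f"configured input does not exist: {config.sites_bed}")

    outdir = nbio.ensure_dir(config.outdir)
    sim_cfg = config.simulation or SimulationConfig()
    sim_cfg.seed = config.seed

    report: Dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "simulate": {},
        "detect": {},
        "classify": {},
        "profile": {},
        "call": {},
        "linkers": {},
        "sites": {},
        "files": {},
    }

    def stage_timer(name):
        start = time.time()
        log.info("stage %s ...", name)
        return lambda: log.info("stage %s done in %.1fs", name, time.time() - start)

    # ---- simulate ---------------------------------------------------------
    done = stage_timer("simulate")
    sim = simulate(sim_cfg)
    paths = write_simulation(sim, outdir)
    report["simulate"] = {
        "n_genes": len(sim.genes),
        "n_barriers": len(sim.truth.barriers),
        "n_true_dyads": len(sim.truth.dyads),
        "n_fragments": len(sim.fragments),
        "n_mnase_tags": len(sim.mnase_tags),
        "n_dnase_tags": len(sim.dnase_tags),
        "class_linker": sim.truth.class_linker,
    }
    report["files"].update(paths)
    done()

    dhss = []
    calls = []
    # ---- detect -----------------------------------------------------------
    if "detect" in config.stages:
        done = stage_timer("detect")
        density = cut_density(sim.dnase_tags, sim.sizes, config.bandwidth)
        rng = np.random.default_rng([71, config.seed])
        randoms = [
            cut_density(
                sample_random_tags(len(sim.dnase_tags), sim.sizes, rng),
                sim.sizes,
                config.bandwidth,
            )
            for _ in range(config.n_random_datasets)
        ]
        try:
            fdr_res = fdr_threshold(
                density, randoms, config.fdr, config.merge_gap, config.min_len,
                conservative=config.fdr_conservative,
            )
        except FdrError:
            raise RuntimeError("detect stage failed: no threshold satisfies the FDR bound")
        dhss = call_dhs(density, fdr_res.threshold, config.merge_gap, config.min_len)
        dhs_path = os.path.join(outdir, "dhs.bed")
        with open(dhs_path, "w") as fh:
            for d in dhss:
                score = int(round(d.summit_density * 1000))
                fh.write(
                    f"{d.chrom}\t{d.start}\t{d.end}\t{d.interval.name}\t{score}\t.\t{d.summit}\n"
                )
        diag_path = os.path.join(outdir, "fdr_thresholds.tsv")
        fdr_res.table.to_csv(diag_path, sep="\t", index=False)
        report["detect"] = {
            "threshold": fdr_res.threshold,
            "n_dhs": len(dhss),
            "mean_random_peaks": fdr_res.mean_random,
            "fdr_ratio": fdr_res.ratio,
            "jaccard_vs_true_barriers": jaccard(
                [d.interval for d in dhss], sim.truth.barriers
            ),
        }
        report["files"]["dhs"] = dhs_path
        report["files"]["fdr_table"] = diag_path
        done()

    # ---- classify ---------------------------------------------------------
    if "classify" in config.stages and dhss:
        done = stage_timer("classify")
        classify_all(dhss, sim.genes)
        summary = category_summary(dhss)
        summary_path = os.path.join(outdir, "category_summary.tsv")
        summary.to_csv(summary_path, sep="\t")
        report["classify"] = {
            "counts": {c: int(summary.loc[c, "count"]) for c in CATEGORY_ORDER},
            "median_length": {
                c: (None if np.isnan(summary.loc[c, "median_length"]) else float(summary.loc[c, "median_length"]))
                for c in CATEGORY_ORDER
            },
        }
        report["files"]["category_summary"] = summary_path
        done()

    # ---- profile ----------------------------------------------------------
    if "profile" in config.stages and dhss:
        done = stage_timer("profile")
        total = len(sim.mnase_tags)
        prof_report = {}
        for cat in CATEGORY_ORDER:
            cat_dhss = [d for d in dhss if d.category == cat]
            if len(cat_dhss) < 3:
                prof_report[cat] = {"n_anchors": len(cat_dhss), "period_left": None, "period_right": None}
                continue
            anchors = anchor_set(cat_dhss, mode="summit")
            prof = strand_profile(
                sim.mnase_tags, anchors, sim.sizes, config.flank, 1, total
            )
            left = oscillation_metrics(prof, "left")
            right = oscillation_metrics(prof, "right")
            prof_report[cat] = {
                "n_anchors": prof.n_anchors,
                "period_left": left.period,
                "period_right": right.period,
            }
            tsv = os.path.join(outdir, f"profile_{cat}.tsv")
            with open(tsv, "w") as fh:
                fh.write("offset\tforward\treverse\n")
                for o, f_, r_ in zip(prof.offsets, prof.forward, prof.reverse):
                    fh.write(f"{o}\t{f_:.6g}\t{r_:.6g}\n")
            report["files"][f"profile_{cat}"] = tsv
        report["profile"] = prof_report
        done()

    # ---- call -------------------------------------------------------------
    if "call" in config.stages:
        done = stage_timer("call")
        dyads, n_discarded = dyad_track(sim.fragments, sim.sizes)
        smoothed = smooth_fft(dyads, config.keep_frac)
        calls = call_nucleosomes(
            smoothed, config.height_quantile, config.min_sep, config.max_phased_width
        )
        nuc_path = os.path.join(outdir, "nucleosomes.bed")
        with open(nuc_path, "w") as fh:
            for i, c in enumerate(calls):
                iv = c.interval
                label = "phased" if c.phased else "fuzzy"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\tnuc{i}_{label}\t"
                    f"{int(round(c.score * 1000))}\t.\n"
                )
        report["call"] = {
            "n_fragments_discarded": n_discarded,
            "n_calls": len(calls),
            "n_phased": sum(1 for c in calls if c.phased),
        }
        report["files"]["nucleosomes"] = nuc_path
        if config.write_tracks:
            for name, track in (("dyads", dyads), ("smoothed", smoothed)):
                p = os.path.join(outdir, f"{name}.bedGraph")
                nbio.write_bedgraph(track, p)
                report["files"][name] = p
        done()

    # ---- linkers ----------------------------------------------------------
    if "linkers" in config.stages and dhss and calls:
        done = stage_timer("linkers")
        total = len(sim.mnase_tags)
        samples: List[LinkerSample] = []
        by_class: Dict[str, Dict[str, LinkerSample]] = {}
        for cat in LINKER_CLASSES:
            cat_dhss = [d for d in dhss if d.category == cat]
            link_rep = {"n_anchors": len(cat_dhss)}
            if len(cat_dhss) < 3:
                by_class[cat] = {}
                report["linkers"][cat] = link_rep
                continue
            anchors = [(d.chrom, d.midpoint, ".") for d in cat_dhss]
            exclude = int(np.percentile([d.length for d in cat_dhss], 90) / 2) + 40
            prof = strand_profile(
                sim.mnase_tags, anchors, sim.sizes, config.flank, 1, total
            )
            a = LinkerSample(
                cat,
                "strand_peak",
                strand_peak_linkers(prof, config.min_peak_sep, exclude_within=exclude),
            )
            spacings, implied = dyad_spacing(
                calls, anchors, config.linker_window, exclude_within=exclude
            )
            b = LinkerSample(cat, "dyad_spacing", spacings)
            samples += [a, b]
            by_class[cat] = {"strand_peak": a, "dyad_spacing": b}
            link_rep.update(
                strand_peak_mean=a.mean if a.n else None,
                strand_peak_n=a.n,
                spacing_mean=b.mean if b.n else None,
                implied_linker_mean=float(np.mean(implied)) if implied.size else None,
                spacing_n=b.n,
            )
            report["linkers"][cat] = link_rep
        # KS comparisons against the intergenic class
        ks_report = {}
        inter = by_class.get("intergenic", {})
        for cat in ("genic", "proximal"):
            other = by_class.get(cat, {})
            for method in ("strand_peak", "dyad_spacing"):
                key = f"intergenic_vs_{cat}_{method}"
                if method in inter and method in other and inter[method].n and other[method].n:
                    res = compare_classes(inter[method], other[method])
                    ks_report[key] = {"D": res.statistic, "p": res.pvalue}
                else:
                    ks_report[key] = None
        report["linkers"]["ks"] = ks_report
        if samples:
            sum_path = os.path.join(outdir, "linker_summary.tsv")
            summarize(samples).to_csv(sum_path, sep="\t", index=False)
            report["files"]["linker_summary"] = sum_path
        done()

    # ---- sites ------------------------------------------------------------
    if "sites" in config.stages and dhss and calls:
        done = stage_timer("sites")
        if config.sites_bed:
            site_set = nbio.read_intervals(config.sites_bed, format="bed6")
        else:
            # demo mode: the true barrier elements stand in for binding sites
            site_set = sim.truth.barriers
        report["sites"] = analyze_sites(
            site_set,
            dhss,
            calls,
            sim.sizes,
            flank=config.site_flank,
            n_random=config.n_random_sites,
            seed=np.random.default_rng([83, config.seed]),
        )
        done()

    for name, path in report["files"].items():
        report["files"][name] = {"path": path, "sha256": _checksum(path)}

    report_path = os.path.join(outdir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    log.info(
        "pipeline finished in %.1fs; report at %s", time.time() - t0, report_path
    )
    return report
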