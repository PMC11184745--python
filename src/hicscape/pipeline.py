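"""End-to-end three-stage analysis pipeline.

From one config (or its defaults) the pipeline simulates a nascent /
fetal / adult stage series with planted structure, equalizes depth across
stages, and runs every analysis layer at its working resolution —
disorder metrics and compartments on 100 kb maps, insulation/TADs at
50 kb, loops at 10 kb — ending in a machine-readable summary JSON and
per-stage text outputs. All randomness derives from the single config
seed, so a repeated run is byte-identical.
"""

from __future__ import annotations

import configparser
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import compartments as comp
from . import domains, elements, global_structure as gs, loops as lp
from . import tf_anchors as tf
from .contact import coarsen_map, downsample, kr_balance, observed_over_expected
from .genome import GenomeBins
from .simulate import (EffectModel, StageEdit, StructureSpec, make_loop_spec,
                       simulate_annotations, simulate_contact_map,
                       simulate_stage_series)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("nascent", "fetal", "adult")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the packaged three-stage
    simulation study (2 x 20 Mb genome at 50 kb, 5 Mb loop segment at
    10 kb)."""

    seed: int = 0
    outdir: str = "hicscape_out"
    # genome for compartment/TAD layers
    n_chroms: int = 2
    chrom_len: int = 20_000_000
    bin_size: int = 50_000
    # planted structure (adult = full strength)
    contrast: float = 0.6
    tad_factor: float = 3.0
    n_boundaries_per_chrom: int = 9
    block_bins: int = 20
    depth: float = 1_200_000
    noise_sigma: float = 0.2
    # stage weakening and switching (nascent is the relaxed stage)
    nascent_structure_scale: float = 0.3
    fetal_structure_scale: float = 0.9
    switch_frac_nascent_fetal: float = 0.18
    switch_frac_fetal_adult: float = 0.12
    nascent_depth: float = 1_000_000
    trans_fraction: float = 0.10
    nascent_trans_fraction: float = 0.15
    # loop layer
    loop_bin_size: int = 10_000
    loop_segment_bins: int = 500
    n_loops: int = 30
    loop_intensity: float = 4.0
    loop_depth: float = 5_000_000
    loop_noise_sigma: float = 0.1
    nascent_loop_scale: float = 0.5
    fetal_loop_scale: float = 0.8
    # analysis parameters
    ngroups_saddle: int = 50
    insulation_window: int = 500_000
    loop_fdr: float = 0.1
    apa_flank: int = 10
    top_k_boundaries: int = 1000
    n_rand_enrichment: int = 200
    fpkm_expressed: float = 2.0
    equalize_depth: bool = True

    @classmethod
    def from_ini(cls, path) -> "RunConfig":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        kwargs = {}
        fields = cls.__dataclass_fields__
        for section in cp.sections():
            for key, val in cp[section].items():
                if key not in fields:
                    raise ValueError(f"unknown config field {key!r} in [{section}]")
                typ = fields[key].type
                if typ == "int":
                    kwargs[key] = int(val)
                elif typ == "float":
                    kwargs[key] = float(val)
                elif typ == "bool":
                    kwargs[key] = val.lower() in ("1", "true", "yes")
                else:
                    kwargs[key] = val
        return cls(**kwargs)

    def validate(self) -> None:
        if self.n_chroms < 1:
            raise ValueError("config field n_chroms must be >= 1")
        for name in ("contrast",):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"config field {name} must lie in [0, 1)")
        if self.depth <= 0 or self.loop_depth <= 0:
            raise ValueError("config field depth/loop_depth must be positive")


def _base_spec(cfg: RunConfig, rng: np.random.Generator) -> StructureSpec:
    sizes = {f"chr{k+1}": cfg.chrom_len for k in range(cfg.n_chroms)}
    bins = GenomeBins(sizes, cfg.bin_size)
    labels, bounds = {}, {}
    for chrom in bins.chroms:
        n = bins.n_bins(chrom)
        labels[chrom] = np.where((np.arange(n) // cfg.block_bins) % 2 == 0, "A", "B")
        bounds[chrom] = np.linspace(0, n, cfg.n_boundaries_per_chrom + 2,
                                    dtype=int)[1:-1]
    return StructureSpec(
        bins=bins, compartment_labels=labels, contrast=cfg.contrast,
        tad_boundaries=bounds, tad_factor=cfg.tad_factor, depth=cfg.depth,
        noise_sigma=cfg.noise_sigma, trans_fraction=cfg.trans_fraction,
    )


def _stage_edits(cfg: RunConfig, base: StructureSpec,
                 rng: np.random.Generator) -> list[StageEdit]:
    """Adult is the base; fetal flips a fraction of labels and softens
    structure slightly; nascent flips more and is strongly relaxed.
    Flips act on whole compartment blocks — megabase-scale switches are
    what eigenvector calling can see — hitting ~``frac`` of bins."""
    def draw_flips(frac: float) -> dict[str, list[int]]:
        flips = {}
        for chrom in base.bins.chroms:
            n = base.bins.n_bins(chrom)
            n_blocks = n // cfg.block_bins
            k = int(round(frac * n_blocks))
            blocks = rng.choice(n_blocks, size=k, replace=False)
            flips[chrom] = sorted(int(i) for b in blocks
                                  for i in range(b * cfg.block_bins,
                                                 min((b + 1) * cfg.block_bins, n)))
        return flips

    fetal_flips = draw_flips(cfg.switch_frac_fetal_adult)
    extra = draw_flips(cfg.switch_frac_nascent_fetal)
    nascent_flips = {c: sorted(set(fetal_flips[c]) ^ set(extra[c]))
                     for c in base.bins.chroms}
    s_n, s_f = cfg.nascent_structure_scale, cfg.fetal_structure_scale
    return [
        StageEdit(contrast_scale=s_n, tad_scale=s_n, label_flips=nascent_flips,
                  depth=cfg.nascent_depth, trans_fraction=cfg.nascent_trans_fraction),
        StageEdit(contrast_scale=s_f, tad_scale=s_f, label_flips=fetal_flips),
        StageEdit(),
    ]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict and writes
    ``summary.json`` plus per-stage text outputs under ``cfg.outdir``."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    summary: dict = {"seed": cfg.seed, "stages": list(STAGES)}

    # --- simulate the 50 kb stage series -------------------------------------
    base = _base_spec(cfg, rng)
    edits = _stage_edits(cfg, base, rng)
    stage_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=3)]
    specs, maps50 = simulate_stage_series(base, edits, stage_seeds)

    if cfg.equalize_depth:
        totals = [int(m.total()) for m in maps50]
        target = min(totals)
        maps50 = [downsample(m, target, seed=stage_seeds[k] + 1)
                  for k, m in enumerate(maps50)]
        summary["equalized_depth"] = target

    # --- global metrics ------------------------------------------------------
    dmax = min(cfg.chrom_len, 50_000_000)
    curves = [gs.contact_decay_curve(m, dmin=2 * cfg.bin_size, dmax=dmax)
              for m in maps50]
    summary["jsd"] = {
        "nascent_vs_fetal": gs.jensen_shannon_divergence(curves[0], curves[1]),
        "fetal_vs_adult": gs.jensen_shannon_divergence(curves[1], curves[2]),
    }
    maps100 = [coarsen_map(m, 2) for m in maps50]
    summary["vne"] = {}
    for stage, m in zip(STAGES, maps100):
        vals = [gs.von_neumann_entropy(m, c) for c in m.bins.chroms]
        summary["vne"][stage] = float(np.mean(vals))
    summary["trans_fraction"] = {
        stage: gs.cis_trans_ratio(m) for stage, m in zip(STAGES, maps50)}

    # --- annotations shared across layers ------------------------------------
    ann_seed = int(rng.integers(0, 2**31 - 1))
    ann = simulate_annotations(specs[2], EffectModel(), seed=ann_seed)
    density = comp.gene_density_track(ann.tss, maps100[0].bins)

    # --- compartments at 100 kb ----------------------------------------------
    profiles, oes = [], []
    for stage, m in zip(STAGES, maps100):
        bal = kr_balance(m)
        oe = observed_over_expected(bal)
        prof = comp.call_compartments(oe, density, stage=stage)
        oes.append(oe)
        profiles.append(prof)
        _write_e1(prof, out / f"compartments_{stage}.bedgraph")
    summary["compartment_strength"] = {}
    for stage, oe, prof in zip(STAGES, oes, profiles):
        vals = [comp.compartment_strength(oe, prof, c) for c in oe.bins.chroms]
        summary["compartment_strength"][stage] = float(np.nanmean(vals))
    summary["saddle_corners"] = {
        stage: comp.saddle(oe, prof, ngroups=cfg.ngroups_saddle).corner_summaries
        for stage, oe, prof in zip(STAGES, oes, profiles)}
    sw_nf = comp.compartment_switches(profiles[0], profiles[1])
    sw_fa = comp.compartment_switches(profiles[1], profiles[2])
    summary["switch_fractions"] = {
        "nascent_to_fetal": comp.switch_fractions(sw_nf),
        "fetal_to_adult": comp.switch_fractions(sw_fa),
    }

    # --- TADs at 50 kb -------------------------------------------------------
    tracks = []
    for stage, m in zip(STAGES, maps50):
        bal = kr_balance(m)
        track = domains.call_boundaries(
            domains.insulation_score(bal, window=cfg.insulation_window))
        tracks.append(track)
        _write_track(track, out, stage)
    summary["n_tads"] = {stage: sum(len(v) for v in tr.tads.values())
                         for stage, tr in zip(STAGES, tracks)}
    summary["n_boundaries"] = {stage: sum(len(v) for v in tr.boundaries.values())
                               for stage, tr in zip(STAGES, tracks)}
    summary["mean_boundary_is"] = {
        stage: float(np.mean(np.concatenate(
            [tr.score[c][tr.boundaries[c]] for c in tr.score
             if tr.boundaries[c].size]) if any(tr.boundaries[c].size for c in tr.score)
            else np.array([np.nan])))
        for stage, tr in zip(STAGES, tracks)}
    shared = domains.shared_tads(domains.tads_to_frame(tracks[1]),
                                 domains.tads_to_frame(tracks[2]))
    summary["shared_tads_fetal_adult"] = shared["n_shared"]
    var = domains.boundary_variability(tracks, top_k=cfg.top_k_boundaries)
    summary["n_variable_boundaries"] = int(len(var))
    var.drop(columns=["cluster"]).assign(cluster=var["cluster"]).to_csv(
        out / "variable_boundaries.tsv", sep="\t", index=False)

    # --- loops at 10 kb ------------------------------------------------------
    loop_seed = int(rng.integers(0, 2**31 - 1))
    loop_base = make_loop_spec(n_bins=cfg.loop_segment_bins, n_loops=cfg.n_loops,
                               bin_size=cfg.loop_bin_size,
                               intensity=cfg.loop_intensity,
                               depth=cfg.loop_depth,
                               noise_sigma=cfg.loop_noise_sigma, seed=loop_seed)
    loop_edits = [StageEdit(loop_scale=cfg.nascent_loop_scale),
                  StageEdit(loop_scale=cfg.fetal_loop_scale), StageEdit()]
    loop_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=3)]
    _lspecs, lmaps = simulate_stage_series(loop_base, loop_edits, loop_seeds)
    lbal = [kr_balance(m) for m in lmaps]
    called = {stage: lp.call_loops(b, fdr=cfg.loop_fdr)
              for stage, b in zip(STAGES, lbal)}
    summary["n_loops"] = {stage: len(s) for stage, s in called.items()}
    adult_loops = called["adult"]
    if len(adult_loops):
        adult_loops.to_bedpe(out / "loops_adult.bedpe")
        _mat, apa_score = lp.apa(lbal[2], adult_loops, flank=cfg.apa_flank)
        summary["apa_score_adult"] = apa_score
        summary["shared_loops_fetal_adult"] = lp.shared_loops(
            called["fetal"], adult_loops)["n_shared"]
        summary["loop_cosine"] = {
            "nascent_vs_fetal": lp.loop_contact_similarity(lbal[0], lbal[1], adult_loops),
            "fetal_vs_adult": lp.loop_contact_similarity(lbal[1], lbal[2], adult_loops),
        }

    # --- elements and TF occupancy on the loop genome ------------------------
    tf_seed = int(rng.integers(0, 2**31 - 1))
    lann = simulate_annotations(loop_base, EffectModel(), seed=tf_seed)
    sizes = loop_base.bins.chrom_sizes
    enh = elements.define_enhancers(lann.h3k27ac_peaks, lann.h3k4me3_peaks)
    proms = elements.promoter_regions(lann.tss, sizes)
    if len(adult_loops):
        classified = lp.classify_anchors(adult_loops, enh, proms)
        summary["loop_classes"] = {
            k: int(v) for k, v in
            classified["loop_class"].value_counts().sort_index().items()}
        expr = lann.expression["adult"]
        lge = lp.loop_gene_expression(adult_loops, proms, expr)
        summary["loop_gene_expression"] = {
            "median_in": lge["median_in"], "median_out": lge["median_out"],
            "p_value": lge["p_value"]}
        enr = tf.anchor_peak_enrichment(
            lann.tf_peaks, adult_loops.anchors_bed(), sizes,
            n_rand=cfg.n_rand_enrichment, seed=tf_seed + 1)
        summary["tf_anchor_enrichment"] = {
            "observed": enr["observed"],
            "background_mean": float(np.mean(enr["background"])),
            "p_value": enr["p_value"]}
        occ = tf.classify_gene_occupancy(adult_loops, proms, lann.tf_peaks)
        occ_sum = tf.occupancy_expression_summary(occ, expr,
                                                  fpkm_expressed=cfg.fpkm_expressed)
        summary["occupancy"] = {
            cls: {"n": d["n"], "expressed_fraction": d["expressed_fraction"],
                  "median_expressed": d["median_expressed"]}
            for cls, d in occ_sum["classes"].items()}
        summary["occupancy_tests"] = occ_sum["tests"]
        oe_scores = (adult_loops.loops["observed"]
                     / adult_loops.loops["expected"]).to_numpy()
        lsbo = tf.loop_score_by_occupancy(oe_scores, adult_loops, lann.tf_peaks)
        summary["loop_score_by_occupancy"] = {str(k): v
                                              for k, v in lsbo["medians"].items()}

    summary = _jsonify(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write("hicscape pipeline\n")
        for key, val in vars(cfg).items():
            fh.write(f"{key} = {val}\n")
    return summary


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if f != f else round(f, 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _write_e1(prof, path) -> None:
    bs = prof.bins.bin_size
    with open(path, "w") as fh:
        for chrom in prof.bins.chroms:
            for i, v in enumerate(prof.e1[chrom]):
                if np.isfinite(v):
                    fh.write(f"{chrom}\t{i*bs}\t{(i+1)*bs}\t{v:.6g}\n")


def _write_track(track, outdir: Path, stage: str) -> None:
    bs = track.bins.bin_size
    with open(outdir / f"insulation_{stage}.bedgraph", "w") as fh:
        for chrom in track.bins.chroms:
            for i, v in enumerate(track.score[chrom]):
                if np.isfinite(v):
                    fh.write(f"{chrom}\t{i*bs}\t{(i+1)*bs}\t{v:.6g}\n")
    domains.tads_to_frame(track).to_csv(outdir / f"tads_{stage}.bed",
                                        sep="\t", header=False, index=False)
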