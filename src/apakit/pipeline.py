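"""End-to-end orchestration: simulate every input, run every stage,
and score recovery of the planted truth.

The demo is the package's integration surface: one seed drives all
generators (via :func:`apakit.synthetic.stage_seed`), every stage runs
with the default (study) parameters, and the report compares planted
against recovered values per stage.  Any failed recovery check makes
the run report failure (the CLI exits non-zero).
"""

from __future__ import annotations

import hashlib
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import concordance, event_tables, genomic_io, interactome, motif_profile, synthetic

logger = logging.getLogger("apakit")


@dataclass
class RunConfig:
    """Pipeline parameters; the defaults are the study's stated values."""

    flank: int = 100
    motifs: tuple[str, ...] = motif_profile.DEFAULT_PAS_MOTIFS
    smooth_window: int = 11
    n_perm: int = 1000
    fdr: float = 0.05
    dppau_thresholds: tuple[float, float] = (0.0, 20.0)
    min_peptides: int = 4
    min_coverage_pct: float = 20.0
    max_p: float = 0.05
    min_log2fc: float = 1.0
    concordance_p: float = 0.05
    concordance_mode: str = "both"
    seed: int = 17
    outdir: str = "demo_out"
    # synthetic-study sizes
    genome_length: int = 100_000
    n_sites: int = 500
    site_len: int = 20
    pas_offset_mean: int = 20
    pas_offset_sd: float = 5.0
    planting_prob: float = 0.5
    cofactor_offset: int = 7
    n_splice_events: int = 500
    n_ppau_events: int = 2000
    ppau_per_group: int = 5
    ppau_frac_shifted: float = 0.2
    ppau_effect: float = 30.0
    ppau_noise_sd: float = 2.0
    n_proteins: int = 600
    n_true_interactors: int = 25
    quant_reps: int = 3
    quant_effect_log2: float = 3.0
    quant_noise_sd_log2: float = 0.2
    n_fc_genes: int = 2000
    fc_r_true: float = 0.30

    def hash(self) -> str:
        params = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = repr(sorted(params.items())).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header_comments(self) -> list[str]:
        return [f"config_hash={self.hash()} seed={self.seed}"]


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a flat key:value (YAML-style) config file; explicit keyword
    overrides win over the file, the file over the defaults."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    for key, cast in (("motifs", str), ("dppau_thresholds", float)):
        if key in merged and isinstance(merged[key], (list, str)):
            value = merged[key]
            if isinstance(value, str):
                value = value.split(",")
            merged[key] = tuple(cast(v) for v in value)
    return RunConfig(**merged)


def write_table(df: pd.DataFrame, path: str | Path, comments=()) -> None:
    with open(path, "w", newline="\n") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


@dataclass
class StageCheck:
    stage: str
    metric: str
    planted: object
    recovered: object
    passed: bool


@dataclass
class DemoReport:
    checks: list[StageCheck] = field(default_factory=list)

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": c.stage,
                    "metric": c.metric,
                    "planted": c.planted,
                    "recovered": c.recovered,
                    "pass": c.passed,
                }
                for c in self.checks
            ]
        )


#: uniform-background expectation: 5 hexamers, each hits with prob 4^-6
UNIFORM_HEXAMER_DENSITY = 5 * 0.25**6


def eligible_mean_density(profile: motif_profile.PositionalProfile, motif_len: int = 6) -> float:
    """Mean raw density over offsets where a full motif fits."""
    eligible = profile.offsets <= profile.offsets[-1] - (motif_len - 1)
    return float(profile.raw_density[eligible].mean())


def run_demo(config: RunConfig | None = None) -> tuple[DemoReport, Path]:
    """Simulate -> profile -> cobind -> splice-filter -> apa -> bioid
    -> concord, scoring recovery at every stage.

    Returns the report and the output directory.  Raises if the output
    directory's parent does not exist.
    """
    cfg = config or RunConfig()
    outdir = Path(cfg.outdir)
    if not outdir.parent.exists():
        raise FileNotFoundError(f"output directory parent does not exist: {outdir.parent}")
    outdir.mkdir(exist_ok=True)
    comments = cfg.header_comments()
    report = DemoReport()
    t0 = time.time()

    def _stage(name):
        logger.info("stage %-14s %6.1fs", name, time.time() - t0)

    # --- simulate genome and binding sites, plant PAS motifs ---
    genome = synthetic.gen_genome(
        cfg.genome_length, seed=synthetic.stage_seed(cfg.seed, "genome")
    )
    sites = synthetic.gen_sites(
        genome, cfg.n_sites, cfg.flank, cfg.site_len,
        seed=synthetic.stage_seed(cfg.seed, "sites"),
    )
    planted_genome, pas_truth = synthetic.plant_pas(
        genome, sites,
        offset_mean=cfg.pas_offset_mean, offset_sd=cfg.pas_offset_sd,
        planting_prob=cfg.planting_prob, flank=cfg.flank,
        seed=synthetic.stage_seed(cfg.seed, "pas"),
    )
    genomic_io.write_genome(planted_genome, outdir / "genome.fa")
    genomic_io.write_sites(sites, outdir / "sites.bed")
    write_table(pas_truth.to_frame(), outdir / "pas_truth.tsv", comments)
    _stage("simulate")

    # --- positional PAS-motif profile with permutation z ---
    perm_seed = synthetic.stage_seed(cfg.seed, "pas") % 2**31
    windows, n_dropped = motif_profile.extract_flanks(sites, planted_genome, cfg.flank)
    profile = motif_profile.permutation_z(
        windows, cfg.motifs, n_perm=cfg.n_perm, seed=perm_seed
    )
    profile = motif_profile.smooth_profile(profile, cfg.smooth_window)
    genomic_io.write_profile(profile, outdir / "profile.tsv", comments)
    peak = profile.argmax_offset(smoothed=True)
    peak_z = float(np.max(profile.z))
    report.checks.append(
        StageCheck("profile", "smoothed_argmax_offset", cfg.pas_offset_mean, peak,
                   abs(peak - cfg.pas_offset_mean) <= 3)
    )
    report.checks.append(
        StageCheck("profile", "peak_z", ">=5", round(peak_z, 2), peak_z >= 5.0)
    )
    report.checks.append(
        StageCheck("profile", "n_dropped_windows", 0, n_dropped, n_dropped == 0)
    )

    # unplanted control: background density and quiet z landscape
    bg_windows, _ = motif_profile.extract_flanks(sites, genome, cfg.flank)
    bg_profile = motif_profile.permutation_z(
        bg_windows, cfg.motifs, n_perm=cfg.n_perm, seed=perm_seed + 1
    )
    bg_mean = eligible_mean_density(bg_profile)
    n_elig = 2 * cfg.flank - 5
    se = math.sqrt(
        UNIFORM_HEXAMER_DENSITY * (1 - UNIFORM_HEXAMER_DENSITY)
        / (len(bg_windows) * n_elig)
    )
    report.checks.append(
        StageCheck(
            "profile", "background_mean_density",
            round(UNIFORM_HEXAMER_DENSITY, 7), round(bg_mean, 7),
            abs(bg_mean - UNIFORM_HEXAMER_DENSITY) <= 3 * se,
        )
    )
    frac_quiet = float(np.mean(np.abs(bg_profile.z) < 3))
    report.checks.append(
        StageCheck("profile", "background_frac_|z|<3", ">=0.95",
                   round(frac_quiet, 4), frac_quiet >= 0.95)
    )
    _stage("profile")

    # --- cross-factor binding profile ---
    queries = synthetic.shift_sites(sites, cfg.cofactor_offset)
    xprof = motif_profile.cross_site_profile(sites, queries, cfg.flank)
    genomic_io.write_profile(xprof, outdir / "cobind.tsv", comments)
    xpeak = xprof.argmax_offset(smoothed=False)
    report.checks.append(
        StageCheck("cobind", "peak_offset", cfg.cofactor_offset, xpeak,
                   xpeak == cfg.cofactor_offset)
    )
    # every anchor contributes its own shifted partner at +offset;
    # incidental same-strand neighbours may add a little on top
    report.checks.append(
        StageCheck("cobind", "peak_density", ">=1.0", xprof.density_at(xpeak),
                   xprof.density_at(xpeak) >= 1.0)
    )
    _stage("cobind")

    # --- splice-event filter ---
    splice, splice_truth = synthetic.gen_splice_events(
        cfg.n_splice_events, seed=synthetic.stage_seed(cfg.seed, "splice")
    )
    kept = event_tables.filter_splice_events(splice, cfg.fdr)
    write_table(kept, outdir / "splice_kept.tsv", comments)
    tally = event_tables.tally_event_types(kept)
    write_table(
        pd.DataFrame(sorted(tally.items()), columns=["type", "count"]),
        outdir / "splice_tally.tsv", comments,
    )
    kept_match = set(kept["event_id"]) == set(splice_truth.kept_event_ids)
    report.checks.append(
        StageCheck("splice", "kept_set_matches_truth",
                   len(splice_truth.kept_event_ids), len(kept), kept_match)
    )
    _stage("splice")

    # --- dPPAU classification ---
    ppau, ppau_truth = synthetic.gen_ppau(
        cfg.n_ppau_events, cfg.ppau_per_group, cfg.ppau_frac_shifted,
        cfg.ppau_effect, cfg.ppau_noise_sd,
        seed=synthetic.stage_seed(cfg.seed, "ppau"),
    )
    dresult = event_tables.compute_dppau(ppau)
    counts = event_tables.classify_dppau(dresult, cfg.dppau_thresholds)
    write_table(dresult.table, outdir / "dppau.tsv", comments)
    t_hi = max(cfg.dppau_thresholds)
    up = set(dresult.table.loc[dresult.table["dppau"] > t_hi, "event_id"])
    down = set(dresult.table.loc[dresult.table["dppau"] < -t_hi, "event_id"])
    apa_match = up == set(ppau_truth.shifted_up_ids) and down == set(
        ppau_truth.shifted_down_ids
    )
    report.checks.append(
        StageCheck(
            "apa", f"shift_sets_recovered_t>{t_hi:g}",
            len(ppau_truth.shifted_up_ids) + len(ppau_truth.shifted_down_ids),
            len(up) + len(down), apa_match,
        )
    )
    mono = all(
        counts[t_hi][k] <= counts[min(cfg.dppau_thresholds)][k]
        for k in ("proximal_up", "proximal_down")
    )
    report.checks.append(
        StageCheck("apa", "counts_monotone_in_threshold", True, mono, mono)
    )
    _stage("apa")

    # --- BioID shortlist ---
    quant, bait_cols, ctrl_cols, quant_truth = synthetic.gen_quant(
        cfg.n_proteins, cfg.n_true_interactors, cfg.quant_reps,
        cfg.quant_effect_log2, cfg.quant_noise_sd_log2,
        seed=synthetic.stage_seed(cfg.seed, "quant"),
    )
    th = interactome.ShortlistThresholds(
        cfg.min_peptides, cfg.min_coverage_pct, cfg.max_p, cfg.min_log2fc
    )
    short = interactome.shortlist(quant, bait_cols, ctrl_cols, th)
    write_table(short, outdir / "shortlist.tsv", comments)
    hits = set(short.loc[short["passes"], "protein_id"])
    truth_set = set(quant_truth.true_interactor_ids)
    recall = len(hits & truth_set) / len(truth_set)
    n_fp = len(hits - truth_set)
    fp_budget = max(1, int(0.01 * (cfg.n_proteins - cfg.n_true_interactors)))
    report.checks.append(
        StageCheck("bioid", "interactor_recall", 1.0, recall, recall == 1.0)
    )
    report.checks.append(
        StageCheck("bioid", "false_positives", f"<={fp_budget}", n_fp,
                   n_fp <= fp_budget)
    )
    _stage("bioid")

    # --- fold-change concordance ---
    fca, fcb, fc_truth = synthetic.gen_fc_pair(
        cfg.n_fc_genes, cfg.fc_r_true, seed=synthetic.stage_seed(cfg.seed, "fcpair")
    )
    conc = concordance.fc_concordance(fca, fcb, cfg.concordance_p, cfg.concordance_mode)
    write_table(
        pd.DataFrame([conc.__dict__]), outdir / "concordance.tsv", comments
    )
    report.checks.append(
        StageCheck("concord", "pearson_r", cfg.fc_r_true, round(conc.pearson_r, 4),
                   abs(conc.pearson_r - cfg.fc_r_true) <= 0.05)
    )
    _stage("concord")

    write_table(report.to_frame(), outdir / "report.tsv", comments)
    logger.info("demo %s in %.1fs", "PASSED" if report.all_passed else "FAILED",
                time.time() - t0)
    return report, outdir
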