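"""Synthetic data with known ground truth for every pipeline input.

Every generator is a pure function of its parameters and a seed, and
returns the planted truth alongside the data, so recovery can be
scored without re-running the generator.  A single master seed derives
per-stage seeds deterministically (see :func:`stage_seed`), so a whole
pipeline run needs one ``--seed`` flag.

What is emulated, and what is not: binding sites are placed uniformly
on an i.i.d. random genome with polyA-signal hexamers written at a
normally distributed downstream offset on the transcript strand;
proximal-usage (PPAU) tables get a fixed fraction of truly shifted
events with symmetric shift directions and Gaussian measurement noise;
quant tables get true interactors with a clean log2 intensity effect;
fold-change pairs are bivariate normal with a chosen correlation.
Real CLIP peak-width/GC structure, compositional PPAU constraints and
MS missingness mechanisms are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import GenomeSequence, Site, SiteSet, reverse_complement
from .motif_profile import anchor_position

BASES = np.array(list("ACGT"))

STAGES = (
    "genome", "sites", "pas", "cofactor", "splice", "ppau", "quant", "fcpair",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage integer seed from the master seed.

    Hashes ``(master, index(stage))`` through numpy's SeedSequence so
    stages draw independent streams and adding a stage never disturbs
    the others.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(master_seed), STAGES.index(stage)])
    return int(ss.generate_state(1)[0])


@dataclass
class SyntheticTruth:
    """Planted parameters and realisations for recovery scoring."""

    seed: int
    pas_offset_mean: int | None = None
    pas_offset_sd: float | None = None
    planting_prob: float | None = None
    planted_site_ids: list[str] = field(default_factory=list)
    planted_offsets: dict[str, int] = field(default_factory=dict)
    cofactor_offset: int | None = None
    kept_event_ids: list[str] = field(default_factory=list)
    shifted_up_ids: list[str] = field(default_factory=list)
    shifted_down_ids: list[str] = field(default_factory=list)
    true_interactor_ids: list[str] = field(default_factory=list)
    true_pearson_r: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a two-column key/value frame (TSV-serialisable)."""
        rows = [("seed", self.seed)]
        for key in (
            "pas_offset_mean", "pas_offset_sd", "planting_prob",
            "cofactor_offset", "true_pearson_r",
        ):
            value = getattr(self, key)
            if value is not None:
                rows.append((key, value))
        for key in (
            "planted_site_ids", "kept_event_ids", "shifted_up_ids",
            "shifted_down_ids", "true_interactor_ids",
        ):
            ids = getattr(self, key)
            if ids:
                rows.append((key, ",".join(map(str, ids))))
        if self.planted_offsets:
            rows.append(
                ("planted_offsets",
                 ",".join(f"{k}:{v}" for k, v in self.planted_offsets.items()))
            )
        return pd.DataFrame(rows, columns=["key", "value"])


def gen_genome(
    length: int,
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    contig: str = "chrS",
) -> GenomeSequence:
    """i.i.d. random genome of one contig."""
    if length < 1:
        raise ValueError("length must be >= 1")
    probs = np.asarray(base_probs, dtype=float)
    if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ValueError("base_probs must be 4 non-negative numbers summing to 1")
    rng = np.random.default_rng(seed)
    seq = "".join(BASES[rng.choice(4, size=length, p=probs)])
    genome = GenomeSequence()
    genome[contig] = seq
    return genome


def gen_sites(
    genome: GenomeSequence,
    n: int,
    flank: int = 100,
    site_len: int = 20,
    seed: int = 0,
) -> SiteSet:
    """Uniformly placed strand-random sites whose flank windows never
    cross a contig boundary (no window is dropped downstream)."""
    contig = next(iter(genome))
    length = len(genome[contig])
    # anchor must satisfy window bounds on either strand, whole site in-contig
    lo = flank + site_len
    hi = length - flank - site_len
    if hi <= lo and n > 0:
        raise ValueError(f"contig too short ({length}) for {n} non-edge sites")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        anchor = int(rng.integers(lo, hi))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = anchor, anchor + site_len
        else:
            start, end = anchor - site_len + 1, anchor + 1
        records.append(Site(contig, start, end, f"site{i:05d}", 0.0, strand))
    return SiteSet(records)


def plant_pas(
    genome: GenomeSequence,
    sites: SiteSet,
    motif: str = "AATAAA",
    offset_mean: int = 20,
    offset_sd: float = 5.0,
    planting_prob: float = 0.5,
    flank: int = 100,
    seed: int = 0,
) -> tuple[GenomeSequence, SyntheticTruth]:
    """Write ``motif`` into a random subset of site windows.

    Each site is independently selected with probability
    ``planting_prob``; a selected site has the motif written starting
    at RNA-orientation offset ``round(Normal(mean, sd))`` from its
    anchor.  Minus-strand plants write the reverse complement at the
    mirrored genomic coordinates.  Offsets whose motif span would leave
    the window are redrawn (up to 100 attempts).
    """
    motif = motif.upper()
    if not 0.0 <= planting_prob <= 1.0:
        raise ValueError("planting_prob must be in [0, 1]")
    if offset_mean + len(motif) > flank:
        raise ValueError("offset_mean + motif length must fit inside the flank")
    rng = np.random.default_rng(seed)
    contig = next(iter(genome))
    seq = list(genome[contig])
    truth = SyntheticTruth(
        seed=seed,
        pas_offset_mean=offset_mean,
        pas_offset_sd=offset_sd,
        planting_prob=planting_prob,
    )
    for site in sites:
        if rng.random() >= planting_prob:
            continue
        for attempt in range(100):
            offset = int(round(rng.normal(offset_mean, offset_sd)))
            if -flank <= offset and offset + len(motif) <= flank:
                break
        else:
            raise RuntimeError("could not draw an in-window offset in 100 attempts")
        anchor = anchor_position(site)
        if site.strand == "+":
            g_start = anchor + offset
            seq[g_start : g_start + len(motif)] = motif
        else:
            # RNA offset o reads the complement of genome[anchor - o]
            g_start = anchor - offset - len(motif) + 1
            seq[g_start : g_start + len(motif)] = reverse_complement(motif)
        truth.planted_site_ids.append(site.name)
        truth.planted_offsets[site.name] = offset
    out = GenomeSequence()
    out[contig] = "".join(seq)
    return out, truth


def shift_sites(sites: SiteSet, offset: int, suffix: str = "_q") -> SiteSet:
    """Query sites whose anchors sit ``offset`` nt downstream (RNA
    orientation) of the input anchors — controlled co-factor sites for
    cross-binding profiles."""
    records = []
    for s in sites:
        delta = offset if s.strand == "+" else -offset
        records.append(
            Site(s.contig, s.start + delta, s.end + delta, s.name + suffix,
                 s.score, s.strand)
        )
    return SiteSet(records)


# branch templates: (type, FDR draw, counts draw, should_keep)
def gen_splice_events(
    n_events: int = 500, seed: int = 0
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Splice-event table with rows drawn from known filter branches.

    Rows are sampled from templates that pin one branch of the
    junction-support filter each (significant + supported, significant
    but under-read, supported but non-significant, ...), so the kept
    set is known by construction.
    """
    rng = np.random.default_rng(seed)
    types = np.array(["SE", "MXE", "RI", "A3SS", "A5SS"])
    rows, kept = [], []
    for i in range(n_events):
        etype = str(rng.choice(types))
        branch = int(rng.integers(0, 4))
        fdr = float(rng.uniform(0.0, 0.049)) if branch < 3 else float(rng.uniform(0.05, 1.0))
        if etype in ("A3SS", "A5SS"):
            if branch == 0:          # sum >= 10
                counts = rng.integers(4, 30, size=3)
                while counts.sum() < 10:
                    counts = rng.integers(4, 30, size=3)
                keep = True
            elif branch in (1, 2):   # sum < 10
                counts = rng.integers(0, 4, size=3)
                keep = False
            else:                    # non-significant
                counts = rng.integers(4, 30, size=3)
                keep = False
            ijc1, ijc2, sjc = map(int, counts)
        else:
            if branch == 0:          # SJC >= 10
                ijc1, ijc2 = map(int, rng.integers(0, 5, size=2))
                sjc = int(rng.integers(10, 40))
                keep = True
            elif branch == 1:        # IJC 10/5 rule
                ijc1, ijc2 = int(rng.integers(10, 40)), int(rng.integers(5, 10))
                if rng.random() < 0.5:
                    ijc1, ijc2 = ijc2, ijc1
                sjc = int(rng.integers(0, 10))
                keep = True
            elif branch == 2:        # under-read
                ijc1, ijc2 = int(rng.integers(0, 10)), int(rng.integers(0, 5))
                sjc = int(rng.integers(0, 10))
                keep = False
            else:                    # non-significant but supported
                ijc1, ijc2 = map(int, rng.integers(0, 5, size=2))
                sjc = int(rng.integers(10, 40))
                keep = False
        event_id = f"ev{i:05d}"
        rows.append((event_id, etype, ijc1, ijc2, sjc, fdr))
        if keep:
            kept.append(event_id)
    table = pd.DataFrame(
        rows, columns=["event_id", "type", "IJC_1", "IJC_2", "SJC", "FDR"]
    )
    truth = SyntheticTruth(seed=seed, kept_event_ids=kept)
    return table, truth


def gen_ppau(
    n_events: int = 2000,
    n_per_group: int = 5,
    frac_shifted: float = 0.2,
    effect: float = 30.0,
    noise_sd: float = 2.0,
    baseline: float = 50.0,
    seed: int = 0,
):
    """PPAU table with a planted fraction of truly shifted events.

    Control samples draw baseline + Normal(0, noise_sd); shifted events
    add +/-effect (sign Bernoulli(0.5)) in the condition group.  Values
    are clipped to [0, 100] (rare at the default baseline/noise).
    """
    from .event_tables import PPAUTable

    if not 0.0 <= frac_shifted <= 1.0:
        raise ValueError("frac_shifted must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shifted = int(round(frac_shifted * n_events))
    shifted_idx = rng.choice(n_events, size=n_shifted, replace=False)
    signs = np.zeros(n_events)
    signs[shifted_idx] = np.where(rng.random(n_shifted) < 0.5, 1.0, -1.0)

    ctrl = baseline + rng.normal(0.0, noise_sd, size=(n_events, n_per_group))
    cond = (
        baseline
        + signs[:, None] * effect
        + rng.normal(0.0, noise_sd, size=(n_events, n_per_group))
    )
    ctrl = np.clip(ctrl, 0.0, 100.0)
    cond = np.clip(cond, 0.0, 100.0)

    event_ids = [f"apa{i:05d}" for i in range(n_events)]
    data = pd.DataFrame({"event_id": event_ids, "gene": [f"g{i:05d}" for i in range(n_events)]})
    group_map = {}
    for j in range(n_per_group):
        data[f"ctrl_{j}"] = ctrl[:, j]
        group_map[f"ctrl_{j}"] = "control"
    for j in range(n_per_group):
        data[f"cond_{j}"] = cond[:, j]
        group_map[f"cond_{j}"] = "condition"
    truth = SyntheticTruth(
        seed=seed,
        shifted_up_ids=[event_ids[i] for i in np.flatnonzero(signs > 0)],
        shifted_down_ids=[event_ids[i] for i in np.flatnonzero(signs < 0)],
    )
    return PPAUTable(data=data, group_map=group_map), truth


def gen_quant(
    n_proteins: int = 600,
    n_true: int = 25,
    reps_per_group: int = 3,
    effect_log2: float = 3.0,
    noise_sd_log2: float = 0.2,
    seed: int = 0,
):
    """Protein quant table with planted true interactors.

    log2 intensities are Normal(baseline, noise_sd) with baseline
    Uniform(22, 28) per protein; true interactors gain ``effect_log2``
    in the bait replicates and always carry filter-passing peptide
    counts (>=5) and coverage (>20%); null proteins get mixed evidence.
    """
    if n_true > n_proteins:
        raise ValueError("n_true cannot exceed n_proteins")
    rng = np.random.default_rng(seed)
    ids = [f"P{i:05d}" for i in range(n_proteins)]
    true_idx = rng.choice(n_proteins, size=n_true, replace=False)
    is_true = np.zeros(n_proteins, dtype=bool)
    is_true[true_idx] = True

    baseline = rng.uniform(22.0, 28.0, size=n_proteins)
    bait_log2 = (
        baseline[:, None]
        + is_true[:, None] * effect_log2
        + rng.normal(0.0, noise_sd_log2, size=(n_proteins, reps_per_group))
    )
    ctrl_log2 = baseline[:, None] + rng.normal(
        0.0, noise_sd_log2, size=(n_proteins, reps_per_group)
    )
    peptides = np.where(
        is_true, rng.integers(5, 30, size=n_proteins), rng.integers(0, 30, size=n_proteins)
    )
    coverage = np.where(
        is_true,
        rng.uniform(25.0, 80.0, size=n_proteins),
        rng.uniform(2.0, 60.0, size=n_proteins),
    )
    table = pd.DataFrame(
        {
            "protein_id": ids,
            "razor_unique_peptides": peptides.astype(int),
            "coverage_pct": coverage,
        }
    )
    bait_cols, ctrl_cols = [], []
    for j in range(reps_per_group):
        col = f"bait_{j}"
        table[col] = 2.0 ** bait_log2[:, j]
        bait_cols.append(col)
    for j in range(reps_per_group):
        col = f"ctrl_{j}"
        table[col] = 2.0 ** ctrl_log2[:, j]
        ctrl_cols.append(col)
    truth = SyntheticTruth(
        seed=seed, true_interactor_ids=[ids[i] for i in np.flatnonzero(is_true)]
    )
    return table, bait_cols, ctrl_cols, truth


def gen_fc_pair(
    n_genes: int = 2000, r_true: float = 0.30, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Paired log2FC tables from a bivariate normal with correlation
    ``r_true``; all p-values are set below 0.05 so significance
    filtering is neutral unless exercised deliberately."""
    if not -1.0 <= r_true <= 1.0:
        raise ValueError("r_true must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, r_true], [r_true, 1.0]])
    xy = rng.multivariate_normal([0.0, 0.0], cov, size=n_genes)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    a = pd.DataFrame({"gene_id": genes, "log2fc": xy[:, 0], "p_value": 0.01})
    b = pd.DataFrame({"gene_id": genes, "log2fc": xy[:, 1], "p_value": 0.01})
    truth = SyntheticTruth(seed=seed, true_pearson_r=r_true)
    return a, b, truth
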