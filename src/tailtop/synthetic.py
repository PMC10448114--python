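"""Seeded generator for every pipeline input, with known ground truth.

The generator emulates the statistical structure of a neuronal
differentiation study of mouse P19 stem cells:

* **Tail tables** — each transcript's poly(A) tail lengths are drawn from a
  three-component Gaussian mixture (short ≲30 nt, ~60 nt, ~120 nt bands;
  truncated at 0 by resampling) plus Gaussian measurement noise, matching
  the bimodal ~60/~120 nt profile of nanopore direct-RNA tail calls.  TOP
  transcripts shift mixture weight from the ~120-nt to the ~60-nt component
  early in differentiation and from ~60 nt to <30 nt late — the two-phase
  deadenylation signature the analysis is meant to recover.
* **SLAM time courses** — metabolic-labeling kinetics under a steady-state
  turnover model: the anabolic (pulse) labeled fraction follows
  ``1 − exp(−k_d t)`` and the catabolic (chase) fraction ``exp(−k_d t)``.
  The catabolic t = 0 point plays the role of the saturation anchor the
  normalizer divides by; the generator treats the long (13 h) pre-label as
  fully saturating, so pulse and chase are exactly self-consistent.
  ``conversion_rate`` is modeled on the read level — the fraction of reads
  carrying at least one T→C conversion — with a per-transcript saturation
  value and binomial sampling over ``coverage`` informative reads.
* **Count matrices** — RNA-seq counts are negative binomial around
  condition-specific means; ribosome-footprint (RFP) means are the RNA
  means scaled by ``2^(ΔTE)`` per condition.  Total dispersion is split
  into a biological component shared by the paired RNA/RFP libraries of a
  replicate (same lysate) and an independent technical component.
* **5′UTR sequences** — TOP transcripts start with a C followed by a
  pyrimidine tract of 4–15 nt; non-TOP UTRs start with a purine.

All draws flow from a single :class:`numpy.random.Generator` seeded by the
caller, so any (config, seed) pair regenerates identical truth and data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io_formats import CountMatrix, GeneSets, QcTag, TailRead

__all__ = [
    "TailMixture",
    "TranscriptTruth",
    "SimulationTruth",
    "SimulationConfig",
    "simulate_transcriptome",
    "simulate_tail_reads",
    "simulate_slam_course",
    "simulate_count_matrices",
    "simulate_utr_sequences",
]

LN2 = math.log(2.0)
_FAIL_TAGS = (QcTag.ADAPTER, QcTag.NOREGION, QcTag.SUFFCLIP, QcTag.READ_FAILED_LOAD)


@dataclass(frozen=True)
class TailMixture:
    """Three-component tail-length mixture (short / ~60 nt / ~120 nt)."""

    weights: tuple[float, float, float]
    means: tuple[float, float, float]
    sds: tuple[float, float, float]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be >= 0 and sum to 1")
        if not (self.means[0] < self.means[1] < self.means[2]):
            raise ValueError("mixture means must be ordered short < 60 < 120")


@dataclass
class TranscriptTruth:
    """Ground truth for one simulated transcript."""

    transcript_id: str
    is_top: bool
    excluded: bool
    k_s: float  # synthesis rate, arbitrary units/min (steady state: k_s = mean * k_d)
    k_d: float  # decay rate, 1/min
    half_life_min: float
    baseline_mean: float
    log2fc: float  # RNA accumulation change, last vs first condition
    delta_log2_te: float  # translational-engagement change, last vs first
    saturation_conversion: float  # labeled read fraction at full 4sU saturation
    expression: dict[str, float]  # per-condition mean expression
    tail_mixtures: dict[str, TailMixture]

    def __post_init__(self) -> None:
        if self.k_d <= 0 or self.k_s < 0:
            raise ValueError("rates must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Defaults emulate the study's scale and effect structure.

    Three differentiation stages (D0 undifferentiated, D2 early, D6 late)
    with three biological replicates, ~1000 transcripts of which 10% carry a
    TOP motif.  Decay half-lives are log-uniform over 1–40 h; TOP
    transcripts are drawn from the stable upper range (10–40 h, median
    ~20 h).  TOP effects: mixture-weight transfer w120→w60 early and
    w60→w_short late, transcriptional downregulation (−1 log2) and a gain in
    translational engagement (+0.8 log2 TE).
    """

    n_transcripts: int = 1000
    top_fraction: float = 0.10
    excluded_fraction: float = 0.02
    conditions: tuple[str, ...] = ("D0", "D2", "D6")
    n_replicates: int = 3
    depth: float = 100.0
    # kinetics (minutes)
    half_life_range_min: tuple[float, float] = (60.0, 2400.0)
    top_half_life_range_min: tuple[float, float] = (600.0, 2400.0)
    saturation_conversion_range: tuple[float, float] = (0.25, 0.55)
    slam_background: float = 0.0
    # expression
    baseline_mean: float = 200.0
    baseline_log_sd: float = 1.0
    de_fraction: float = 0.2
    de_log2fc: float = 1.0
    top_log2fc: float = -1.0
    top_delta_log2_te: float = 0.8
    # counts
    dispersion: float = 0.05
    dispersion_biological_fraction: float = 0.6
    library_size_log_sd: float = 0.15
    # tails
    mixture_means: tuple[float, float, float] = (15.0, 60.0, 120.0)
    mixture_sds: tuple[float, float, float] = (8.0, 15.0, 25.0)
    base_weights: tuple[float, float, float] = (0.10, 0.60, 0.30)
    top_w120_to_w60: float = 0.25
    top_w60_to_short: float = 0.20
    tail_noise_sd: float = 5.0
    qc_fail_fraction: float = 0.05
    read_depth_dispersion: float = 0.25
    scale_depth_with_expression: bool = True

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        if not 0 <= self.top_fraction <= 1:
            raise ValueError("top_fraction must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SimulationTruth:
    """Full truth table: per-transcript ground truth plus the run recipe."""

    transcripts: list[TranscriptTruth]
    config: SimulationConfig
    seed: int

    @property
    def conditions(self) -> tuple[str, ...]:
        return self.config.conditions

    @property
    def ids(self) -> list[str]:
        return [t.transcript_id for t in self.transcripts]

    @property
    def top_ids(self) -> set[str]:
        return {t.transcript_id for t in self.transcripts if t.is_top}

    @property
    def excluded_ids(self) -> set[str]:
        return {t.transcript_id for t in self.transcripts if t.excluded}

    def gene_sets(self) -> GeneSets:
        return GeneSets(
            universe=set(self.ids), top_genes=self.top_ids, exclusions=self.excluded_ids
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.transcripts:
            row = {
                "transcript_id": t.transcript_id,
                "is_top": t.is_top,
                "excluded": t.excluded,
                "k_s": t.k_s,
                "k_d_per_min": t.k_d,
                "half_life_min": t.half_life_min,
                "baseline_mean": t.baseline_mean,
                "log2fc": t.log2fc,
                "delta_log2_te": t.delta_log2_te,
                "saturation_conversion": t.saturation_conversion,
            }
            for cond, mix in t.tail_mixtures.items():
                row[f"w_short_{cond}"], row[f"w_60_{cond}"], row[f"w_120_{cond}"] = mix.weights
            rows.append(row)
        return pd.DataFrame(rows)


def _transfer(weights: tuple[float, float, float], src: int, dst: int, amount: float):
    w = list(weights)
    moved = min(amount, w[src])
    w[src] -= moved
    w[dst] += moved
    return tuple(w)


def simulate_transcriptome(config: SimulationConfig | None = None, seed: int = 0) -> SimulationTruth:
    """Draw the per-transcript ground truth for one simulated study.

    The configured TOP fraction is honoured exactly (``round(n * fraction)``
    transcripts are TOP); exclusion flags (mitochondrial/pseudogene stand-ins)
    are assigned among non-TOP transcripts only.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_transcripts
    ids = [f"TX{i:05d}" for i in range(n)]

    n_top = int(round(n * cfg.top_fraction))
    order = rng.permutation(n)
    top_idx = set(order[:n_top].tolist())
    non_top = [i for i in order.tolist() if i not in top_idx]
    n_exc = min(int(round(n * cfg.excluded_fraction)), len(non_top))
    excluded_idx = set(non_top[:n_exc])

    lo, hi = cfg.half_life_range_min
    tlo, thi = cfg.top_half_life_range_min
    half_life = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    half_life_top = np.exp(rng.uniform(math.log(tlo), math.log(thi), size=n))
    baseline = rng.lognormal(math.log(cfg.baseline_mean), cfg.baseline_log_sd, size=n)
    sat = rng.uniform(*cfg.saturation_conversion_range, size=n)

    # differential accumulation: all TOP transcripts down, a configurable
    # fraction of non-TOP transcripts shifted with random sign
    log2fc = np.zeros(n)
    de_draw = rng.random(n) < cfg.de_fraction
    de_sign = rng.choice([-1.0, 1.0], size=n)
    conds = cfg.conditions
    last = conds[-1]

    transcripts: list[TranscriptTruth] = []
    for i in range(n):
        is_top = i in top_idx
        t_half = float(half_life_top[i] if is_top else half_life[i])
        k_d = LN2 / t_half
        if is_top:
            lfc = cfg.top_log2fc
        elif de_draw[i]:
            lfc = float(de_sign[i] * cfg.de_log2fc)
        else:
            lfc = 0.0
        # expression interpolates log-linearly from first to last condition
        expr = {
            c: float(baseline[i] * 2.0 ** (lfc * j / max(len(conds) - 1, 1)))
            for j, c in enumerate(conds)
        }
        mixtures: dict[str, TailMixture] = {}
        for j, c in enumerate(conds):
            w = cfg.base_weights
            if is_top and j >= 1:
                w = _transfer(w, 2, 1, cfg.top_w120_to_w60)  # ~120 -> ~60, early
                if c == last:
                    w = _transfer(w, 1, 0, cfg.top_w60_to_short)  # ~60 -> short, late
            mixtures[c] = TailMixture(weights=w, means=cfg.mixture_means, sds=cfg.mixture_sds)
        transcripts.append(
            TranscriptTruth(
                transcript_id=ids[i],
                is_top=is_top,
                excluded=i in excluded_idx,
                k_s=float(baseline[i] * k_d),
                k_d=float(k_d),
                half_life_min=t_half,
                baseline_mean=float(baseline[i]),
                log2fc=float(lfc),
                delta_log2_te=cfg.top_delta_log2_te if is_top else 0.0,
                saturation_conversion=float(sat[i]),
                expression=expr,
                tail_mixtures=mixtures,
            )
        )
    return SimulationTruth(transcripts=transcripts, config=cfg, seed=int(seed))


def _truncated_mixture_lengths(rng, mix_w, mix_mu, mix_sd, tx_of_read, noise_sd):
    """Vectorized mixture draw with truncation at 0 by resampling."""
    n_reads = tx_of_read.size
    u = rng.random(n_reads)
    cum = np.cumsum(mix_w[tx_of_read], axis=1)
    comp = (u[:, None] > cum).sum(axis=1)
    mu = mix_mu[comp]
    sd = mix_sd[comp]
    lengths = rng.normal(mu, sd)
    if noise_sd > 0:
        lengths = lengths + rng.normal(0.0, noise_sd, size=n_reads)
    bad = lengths < 0
    while bad.any():
        redraw = rng.normal(mu[bad], sd[bad])
        if noise_sd > 0:
            redraw = redraw + rng.normal(0.0, noise_sd, size=bad.sum())
        lengths[bad] = redraw
        bad = lengths < 0
    return lengths


def simulate_tail_reads(
    truth: SimulationTruth,
    condition: str,
    depth: float | None = None,
    seed: int = 0,
    as_frame: bool = False,
    noise_sd: float | None = None,
) -> list[TailRead] | pd.DataFrame:
    """Simulate per-read tail tables for all replicates of one condition.

    Per-transcript read depth is negative-binomial around ``depth`` (scaled
    by relative expression when configured, as capture tracks abundance);
    tail lengths come from the condition's mixture with measurement noise; a
    configured fraction of reads receives non-PASS QC tags.  Set
    ``as_frame`` for a DataFrame in the table dialect instead of
    :class:`TailRead` objects (cheaper for large simulations).
    """
    cfg = truth.config
    if condition not in cfg.conditions:
        raise ValueError(f"unknown condition {condition!r}; have {cfg.conditions}")
    depth = cfg.depth if depth is None else float(depth)
    noise_sd = cfg.tail_noise_sd if noise_sd is None else float(noise_sd)
    rng = np.random.default_rng(seed)

    txs = truth.transcripts
    n_tx = len(txs)
    expr = np.array([t.expression[condition] for t in txs])
    if cfg.scale_depth_with_expression:
        mean_depth = depth * expr / np.exp(np.mean(np.log(expr)))
    else:
        mean_depth = np.full(n_tx, depth)
    mix_w = np.array([t.tail_mixtures[condition].weights for t in txs])
    mix_mu = np.asarray(cfg.mixture_means, dtype=float)
    mix_sd = np.asarray(cfg.mixture_sds, dtype=float)

    frames = []
    for rep in range(1, cfg.n_replicates + 1):
        d = cfg.read_depth_dispersion
        if d > 0:
            n_reads_tx = rng.negative_binomial(1.0 / d, 1.0 / (1.0 + d * mean_depth))
        else:
            n_reads_tx = rng.poisson(mean_depth)
        tx_of_read = np.repeat(np.arange(n_tx), n_reads_tx)
        lengths = _truncated_mixture_lengths(rng, mix_w, mix_mu, mix_sd, tx_of_read, noise_sd)
        lengths = np.round(lengths, 2)
        total = tx_of_read.size
        tags = np.full(total, QcTag.PASS.value, dtype=object)
        fail = rng.random(total) < cfg.qc_fail_fraction
        if fail.any():
            tags[fail] = rng.choice([t.value for t in _FAIL_TAGS], size=int(fail.sum()))
        sample = f"{condition}_rep{rep}"
        frames.append(
            pd.DataFrame(
                {
                    "readname": [f"read_{sample}_{i:07d}" for i in range(total)],
                    "contig": np.array([t.transcript_id for t in txs], dtype=object)[tx_of_read],
                    "sample_id": sample,
                    "condition": condition,
                    "polya_length": lengths,
                    "qc_tag": tags,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if as_frame:
        return df
    from .io_formats import frame_to_tail_reads

    return frame_to_tail_reads(df)


def simulate_slam_course(
    truth: SimulationTruth,
    design: str,
    timepoints_h: Sequence[float] = (0.0, 3.0, 6.0, 9.0),
    coverage: int | None = 200,
    seed: int = 0,
    background: float | None = None,
) -> pd.DataFrame:
    """Simulate a per-transcript T→C conversion time course.

    ``design`` is ``"anabolic"`` (pulse; labeled fraction ``1 − exp(−k_d t)``)
    or ``"catabolic"`` (chase; ``exp(−k_d t)``).  Observed conversion is
    ``background + f · (saturation − background)`` sampled binomially over
    ``coverage`` informative reads; ``coverage=None`` yields the noiseless
    analytic curve.  Time 0 must be present — it anchors the downstream
    saturation normalization.
    """
    if design not in ("anabolic", "catabolic"):
        raise ValueError(f"design must be 'anabolic' or 'catabolic', got {design!r}")
    timepoints_h = tuple(float(t) for t in timepoints_h)
    if 0.0 not in timepoints_h:
        raise ValueError("timepoints must include 0 (saturation anchor)")
    cfg = truth.config
    background = cfg.slam_background if background is None else float(background)
    rng = np.random.default_rng(seed)

    k = np.array([t.k_d for t in truth.transcripts])  # 1/min
    sat = np.array([t.saturation_conversion for t in truth.transcripts])
    ids = np.array(truth.ids, dtype=object)
    rows = []
    for t_h in timepoints_h:
        t_min = t_h * 60.0
        decay = np.exp(-k * t_min)
        f = (1.0 - decay) if design == "anabolic" else decay
        # transcripts whose saturation never rises above background stay flat
        p = np.where(sat > background, background + f * (sat - background), background)
        p = np.clip(p, 0.0, 1.0)
        for rep in range(1, cfg.n_replicates + 1):
            if coverage is None:
                conv = p
            else:
                conv = rng.binomial(int(coverage), p) / float(coverage)
            rows.append(
                pd.DataFrame(
                    {
                        "transcript_id": ids,
                        "design": design,
                        "time_h": t_h,
                        "replicate": rep,
                        "conversion_rate": conv,
                        "coverage": 0 if coverage is None else int(coverage),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def _nb_draw(rng, mean, alpha):
    """NB(mean, dispersion alpha) via numpy; Poisson when alpha == 0."""
    mean = np.maximum(mean, 1e-12)
    if alpha <= 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    return rng.negative_binomial(size, size / (size + mean))


def simulate_count_matrices(
    truth: SimulationTruth,
    conditions: tuple[str, str] | None = None,
    n_replicates: int | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, CountMatrix]:
    """Simulate matched RNA-seq and RFP count matrices for two conditions.

    For each gene/condition/replicate a shared biological factor (gamma with
    mean 1) perturbs the condition mean; the paired RNA and RFP libraries of
    the replicate both see it, on top of independent technical NB noise.
    RFP means equal RNA means times ``2^(ΔTE)`` in the second condition.
    Library size factors are drawn log-normally per library.
    """
    cfg = truth.config
    conds = conditions or (cfg.conditions[0], cfg.conditions[-1])
    n_rep = cfg.n_replicates if n_replicates is None else int(n_replicates)
    if n_rep < 2:
        raise ValueError("at least 2 replicates per condition are required")
    for c in conds:
        if c not in cfg.conditions:
            raise ValueError(f"unknown condition {c!r}")
    rng = np.random.default_rng(seed)

    alpha_bio = cfg.dispersion * cfg.dispersion_biological_fraction
    alpha_tech = cfg.dispersion * (1.0 - cfg.dispersion_biological_fraction)
    genes = truth.ids
    mu = np.array([[t.expression[c] for c in conds] for t in truth.transcripts])
    dte = np.array([t.delta_log2_te for t in truth.transcripts])

    rna_cols, rfp_cols, rna_meta, rfp_meta = {}, {}, [], []
    for j, cond in enumerate(conds):
        te = dte * (j == len(conds) - 1)
        for rep in range(1, n_rep + 1):
            if alpha_bio > 0:
                shape = 1.0 / alpha_bio
                bio = rng.gamma(shape, 1.0 / shape, size=len(genes))
            else:
                bio = 1.0
            sf_rna = rng.lognormal(0.0, cfg.library_size_log_sd)
            sf_rfp = rng.lognormal(0.0, cfg.library_size_log_sd)
            base = mu[:, j] * bio
            rna_name = f"{cond}_rna_r{rep}"
            rfp_name = f"{cond}_rfp_r{rep}"
            rna_cols[rna_name] = _nb_draw(rng, base * sf_rna, alpha_tech)
            rfp_cols[rfp_name] = _nb_draw(rng, base * (2.0 ** te) * sf_rfp, alpha_tech)
            rna_meta.append((rna_name, cond, "rna", rep))
            rfp_meta.append((rfp_name, cond, "rfp", rep))

    def _build(cols, meta):
        meta_df = pd.DataFrame(meta, columns=["sample_id", "condition", "assay", "replicate"])
        meta_df = meta_df.set_index("sample_id")
        return CountMatrix(
            gene_ids=list(genes),
            sample_ids=list(cols),
            counts=np.column_stack(list(cols.values())).astype(np.int64),
            sample_meta=meta_df,
        )

    return _build(rna_cols, rna_meta), _build(rfp_cols, rfp_meta)


_PYR = np.array(list("CU"))
_PUR = np.array(list("AG"))
_ALL = np.array(list("ACGU"))


def simulate_utr_sequences(
    truth: SimulationTruth, seed: int = 0, length: int = 60
) -> list[SeqRecord]:
    """Generate 5′UTR sequences whose TOP status matches the truth labels.

    TOP UTRs begin with C followed by pyrimidines for a total 5′ tract of
    4–15 nt (uniform), terminated by a purine; non-TOP UTRs begin with a
    purine.  RNA alphabet {A, C, G, U}.
    """
    rng = np.random.default_rng(seed)
    records = []
    for t in truth.transcripts:
        if t.is_top:
            run = int(rng.integers(4, 16))
            head = ["C"] + list(rng.choice(_PYR, size=run - 1))
            head.append(str(rng.choice(_PUR)))
        else:
            head = [str(rng.choice(_PUR))]
        tail_len = max(length - len(head), 0)
        seq = "".join(head) + "".join(rng.choice(_ALL, size=tail_len))
        records.append(
            SeqRecord(Seq(seq[:length]), id=t.transcript_id, description=f"top={int(t.is_top)}")
        )
    return records
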