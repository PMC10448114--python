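"""Per-transcript poly(A) tail-length profiles and tail-shift tests.

Reads are binned into three tail-length bands: <30 nt (shorter than one
PABP footprint, decay-prone), 30–90 nt (the "~60 nt" band, one to two
PABPs) and >90 nt (extended tails).  The 30 and 90 nt boundary lengths are
assigned to the ~60 band, matching the inclusive "30- to 90-nt" convention;
the edges are configurable.

Transcripts are profiled only if they carry at least ``min_reads`` PASS
reads pooled over all samples and conditions (default 30) and are not on
the exclusion list (mitochondrial/pseudogene).  Differential accumulation
in a band between two conditions is assessed per transcript by a pooled
two-sample, two-tailed Student's t-test on the per-replicate band
fractions, with a raw p ≤ 0.05 call threshold (no multiple-testing
correction at this stage — the raw threshold is deliberate and documented).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSets, TailRead, tail_reads_to_frame

__all__ = [
    "bin_fractions",
    "build_tail_profiles",
    "relative_frequency_histogram",
    "test_bin_fraction_change",
]

BIN_COLUMNS = {"lt30": "frac_lt30", "about60": "frac_60", "gt90": "frac_gt90"}


def bin_fractions(
    tail_lengths: Sequence[float], edges: tuple[float, float] = (30.0, 90.0)
) -> tuple[float, float, float]:
    """Fractions of tails in [0, lo), [lo, hi] and (hi, inf); sums to 1."""
    lengths = np.asarray(tail_lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("bin_fractions requires at least one tail length")
    if (lengths < 0).any():
        raise ValueError("tail lengths must be non-negative")
    lo, hi = edges
    n = lengths.size
    lt = float(np.count_nonzero(lengths < lo)) / n
    mid = float(np.count_nonzero((lengths >= lo) & (lengths <= hi))) / n
    gt = float(np.count_nonzero(lengths > hi)) / n
    return lt, mid, gt


def _as_frame(reads) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        return reads
    return tail_reads_to_frame(reads)


def build_tail_profiles(
    reads: Iterable[TailRead] | pd.DataFrame,
    gene_sets: GeneSets | None = None,
    min_reads: int = 30,
    edges: tuple[float, float] = (30.0, 90.0),
    max_length: int = 500,
) -> pd.DataFrame:
    """Build one tail profile per retained transcript × sample.

    ``reads`` must already be PASS-filtered.  A transcript is retained iff
    its reads summed over *all* samples and conditions reach ``min_reads``
    and it is not excluded.  Each profile row carries the read count, the
    three band fractions and a per-1-nt histogram (lengths clipped at
    ``max_length`` for the histogram only).
    """
    df = _as_frame(reads)
    if df.empty:
        return pd.DataFrame(
            columns=[
                "transcript_id", "sample_id", "condition", "n_reads",
                "frac_lt30", "frac_60", "frac_gt90", "histogram",
            ]
        )
    if gene_sets is not None and gene_sets.exclusions:
        df = df[~df["contig"].isin(gene_sets.exclusions)]
    totals = df.groupby("contig")["polya_length"].size()
    keep = set(totals.index[totals >= min_reads])
    df = df[df["contig"].isin(keep)]

    rows = []
    for (contig, sample), grp in df.groupby(["contig", "sample_id"], sort=True):
        lengths = grp["polya_length"].to_numpy()
        lt, mid, gt = bin_fractions(lengths, edges)
        hist = np.bincount(
            np.clip(np.rint(lengths).astype(int), 0, max_length), minlength=max_length + 1
        )
        rows.append(
            {
                "transcript_id": contig,
                "sample_id": sample,
                "condition": grp["condition"].iloc[0],
                "n_reads": len(grp),
                "frac_lt30": lt,
                "frac_60": mid,
                "frac_gt90": gt,
                "histogram": hist,
            }
        )
    return pd.DataFrame(rows)


def relative_frequency_histogram(
    profiles: pd.DataFrame,
    condition: str,
    bin_width: int = 1,
    max_length: int = 250,
) -> pd.DataFrame:
    """Transcriptome-wide tail-length relative frequencies for one condition.

    Per replicate, per-1-nt histograms are summed over transcripts, lengths
    above ``max_length`` pooled into the last bin, re-binned at
    ``bin_width`` and normalized to sum to 1; the across-replicate mean is
    reported alongside the per-replicate columns.
    """
    sel = profiles[profiles["condition"] == condition]
    if sel.empty:
        raise ValueError(f"no profiles for condition {condition!r}")
    per_sample = {}
    for sample, grp in sel.groupby("sample_id"):
        total = np.sum(np.stack(grp["histogram"].to_numpy()), axis=0).astype(float)
        if len(total) > max_length + 1:
            total[max_length] += total[max_length + 1 :].sum()
            total = total[: max_length + 1]
        n_bins = int(np.ceil(len(total) / bin_width))
        padded = np.zeros(n_bins * bin_width)
        padded[: len(total)] = total
        binned = padded.reshape(n_bins, bin_width).sum(axis=1)
        per_sample[sample] = binned / binned.sum()
    out = pd.DataFrame(per_sample)
    out.insert(0, "length", np.arange(len(out)) * bin_width)
    out["mean_frequency"] = out.drop(columns="length").mean(axis=1)
    return out


def test_bin_fraction_change(
    profiles: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    bin: str = "about60",
    alpha: float = 0.05,
    welch: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-transcript test for a band-fraction change between two conditions.

    Test units are the per-replicate band fractions; the default test is the
    pooled-variance Student's t (Welch optional).  Returns ``(results,
    skipped)``: transcripts with fewer than two replicates on either side
    are skipped with a reason.  Zero-variance degeneracies yield p = 1 when
    the means agree and p = 0 (flagged) otherwise.

    ``delta`` is ``mean_b − mean_a`` on the proportion scale and
    ``fold_change`` is ``mean_b / mean_a`` (NaN when the baseline mean is 0).
    """
    if bin not in BIN_COLUMNS:
        raise ValueError(f"bin must be one of {sorted(BIN_COLUMNS)}, got {bin!r}")
    col = BIN_COLUMNS[bin]

    results, skipped = [], []
    sub = profiles[profiles["condition"].isin([cond_a, cond_b])]
    for contig, grp in sub.groupby("transcript_id", sort=True):
        fa = grp.loc[grp["condition"] == cond_a, col].to_numpy(dtype=float)
        fb = grp.loc[grp["condition"] == cond_b, col].to_numpy(dtype=float)
        if len(fa) < 2 or len(fb) < 2:
            skipped.append(
                {
                    "transcript_id": contig,
                    "reason": f"<2 replicates (n_a={len(fa)}, n_b={len(fb)})",
                }
            )
            continue
        mean_a, mean_b = float(fa.mean()), float(fb.mean())
        degenerate = (fa == fa[0]).all() and (fb == fb[0]).all()
        if degenerate:
            p = 1.0 if mean_a == mean_b else 0.0
            stat = np.nan
        else:
            with warnings.catch_warnings():
                # near-identical replicate fractions trip scipy's precision
                # warning; the exact-tie case is handled by the branch above
                warnings.simplefilter("ignore", RuntimeWarning)
                stat, p = stats.ttest_ind(fb, fa, equal_var=not welch)
            stat, p = float(stat), float(p)
        results.append(
            {
                "transcript_id": contig,
                "bin": bin,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "n_a": len(fa),
                "n_b": len(fb),
                "delta": mean_b - mean_a,
                "fold_change": mean_b / mean_a if mean_a > 0 else np.nan,
                "t_statistic": stat,
                "p_value": p,
                "significant": p <= alpha,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(results), pd.DataFrame(skipped, columns=["transcript_id", "reason"])
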