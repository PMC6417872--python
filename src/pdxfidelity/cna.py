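"""Copy-number concordance between matched tumors and xenografts.

Segment tables (absolute copy number) are projected onto fixed-width
genomic windows (default 10 kb); tumor-PDX similarity is the Pearson
correlation of the windowed profiles, with matched pairs tested against
all other sample pairs by a one-sided rank-sum test. Focal gene events use
the length-weighted median segment mean over the gene plus 100 kb flanks
(amplified > 3 copies, lost < 1.5); arm-level events call a gain/loss when
at least half of an arm's windows sit beyond 2.5 / 1.5 copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pdxfidelity.stats import rank_sum_test

WINDOW_SIZE = 10_000
FOCAL_FLANK = 100_000
AMP_THRESHOLD = 3.0
LOSS_THRESHOLD = 1.5
ARM_GAIN_CN = 2.5
ARM_LOSS_CN = 1.5
ARM_FRACTION = 0.5


@dataclass
class CopyNumberProfile:
    """Windowed absolute copy number for one sample.

    Windows tile the genome contiguously (0-based half-open; the last
    window of a chromosome may be shorter). `mask` marks windows with no
    segment coverage; masked windows are excluded from all statistics.
    """

    sample: str
    windows: pd.DataFrame  # chrom, start, end
    copy_number: np.ndarray
    mask: np.ndarray  # True where the window has no segment coverage

    def covered_fraction(self) -> float:
        return 1.0 - self.mask.mean() if len(self.mask) else 0.0


def _check_non_overlapping(segments: pd.DataFrame) -> None:
    offenders = []
    for chrom, grp in segments.groupby("chrom"):
        g = grp.sort_values("start")
        prev_end, prev_row = -1, None
        for row in g.itertuples(index=False):
            if row.start < prev_end:
                offenders.append((chrom, prev_row.start, prev_row.end, row.start, row.end))
            prev_end, prev_row = max(prev_end, row.end), row
    if offenders:
        raise ValueError(f"overlapping segments: {offenders[:5]}")


def segments_to_windows(
    segments: pd.DataFrame,
    genome: dict[str, int],
    window_size: int = WINDOW_SIZE,
    sample: str | None = None,
) -> CopyNumberProfile:
    """Project a SEG table onto fixed windows tiling `genome`.

    Each window takes the length-weighted mean of overlapping segment
    means; windows with no overlap are masked. Chromosome-end windows
    shorter than `window_size` are kept at their true width.
    """
    _check_non_overlapping(segments)
    if sample is None:
        samples = segments["sample"].unique() if "sample" in segments.columns else ["sample"]
        if len(samples) != 1:
            raise ValueError("multiple samples in SEG table; pass sample=")
        sample = str(samples[0])

    frames, cn_parts, wt_parts = [], [], []
    for chrom, length in genome.items():
        starts = np.arange(0, length, window_size)
        ends = np.minimum(starts + window_size, length)
        n = len(starts)
        wsum = np.zeros(n)
        wlen = np.zeros(n)
        for seg in segments[segments["chrom"] == chrom].itertuples(index=False):
            s, e = max(seg.start, 0), min(seg.end, length)
            if s >= e:
                continue
            i0, i1 = s // window_size, (e - 1) // window_size
            for i in range(i0, i1 + 1):
                ov = min(e, ends[i]) - max(s, starts[i])
                if ov > 0:
                    wsum[i] += ov * seg.seg_mean
                    wlen[i] += ov
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        with np.errstate(invalid="ignore"):
            cn_parts.append(np.where(wlen > 0, wsum / np.maximum(wlen, 1e-12), np.nan))
        wt_parts.append(wlen)
    windows = pd.concat(frames, ignore_index=True)
    cn = np.concatenate(cn_parts)
    mask = np.isnan(cn)
    return CopyNumberProfile(sample=sample, windows=windows, copy_number=cn, mask=mask)


def cn_correlation_matrix(
    profiles: list[CopyNumberProfile],
    pair_map: dict[str, tuple[str, str]] | None = None,
    min_covered: float = 0.5,
) -> dict:
    """Pairwise Pearson correlation over jointly unmasked windows.

    `pair_map` maps patient id -> (tumor sample, pdx sample); pairs in the
    map are labeled matched, every other off-diagonal pair unmatched.
    Pairs whose joint unmasked overlap covers less than `min_covered` of
    the window grid are flagged with a low-coverage warning (still
    computed). Returns the matrix, matched/unmatched correlation lists,
    and warnings.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    grid = profiles[0].windows
    for p in profiles[1:]:
        if len(p.windows) != len(grid) or not (
            p.windows[["chrom", "start", "end"]].values == grid[["chrom", "start", "end"]].values
        ).all():
            raise ValueError(f"window grid mismatch for sample {p.sample}")
    names = [p.sample for p in profiles]
    n = len(profiles)
    mat = np.eye(n)
    warnings = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~profiles[i].mask & ~profiles[j].mask
            if ok.mean() < min_covered:
                warnings.append(
                    f"pair ({names[i]}, {names[j]}): only {ok.mean():.0%} of windows jointly covered"
                )
            xi = profiles[i].copy_number[ok]
            xj = profiles[j].copy_number[ok]
            if ok.sum() < 2 or np.std(xi) == 0 or np.std(xj) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(xi, xj)[0, 1])
            mat[i, j] = mat[j, i] = r
    matrix = pd.DataFrame(mat, index=names, columns=names)

    matched, unmatched = [], []
    matched_pairs = set()
    if pair_map:
        for t, x in pair_map.values():
            if t in names and x in names:
                matched_pairs.add(frozenset((t, x)))
    for i in range(n):
        for j in range(i + 1, n):
            r = mat[i, j]
            if np.isnan(r):
                continue
            if frozenset((names[i], names[j])) in matched_pairs:
                matched.append(r)
            else:
                unmatched.append(r)
    return {
        "matrix": matrix,
        "matched": matched,
        "unmatched": unmatched,
        "warnings": warnings,
    }


def matched_vs_unmatched_test(matched: list[float], unmatched: list[float]) -> float:
    """One-sided rank-sum p-value for matched correlations exceeding
    unmatched ones (exact for small groups, mid-ranks for ties)."""
    return rank_sum_test(np.asarray(matched), np.asarray(unmatched))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    idx = int(np.searchsorted(cum, half))
    if np.isclose(cum[idx], half) and idx + 1 < len(v):
        return float((v[idx] + v[idx + 1]) / 2.0)
    return float(v[idx])


def focal_gene_calls(
    segments: pd.DataFrame,
    gene_bed: pd.DataFrame,
    flank: int = FOCAL_FLANK,
    amp_threshold: float = AMP_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
    sample: str | None = None,
) -> pd.DataFrame:
    """Gene-level focal amplification/loss calls from a SEG table.

    The statistic is the base-pair length-weighted median segment mean
    over the gene region extended by `flank` on each side (invariant to
    splitting segments). amplified iff median > amp_threshold; lost iff
    median < loss_threshold; else neutral. Genes with no overlapping
    segment are reported with call "uncallable".
    """
    _check_non_overlapping(segments)
    if sample is None:
        sample = str(segments["sample"].iloc[0]) if "sample" in segments.columns else "sample"
    rows = []
    for g in gene_bed.itertuples(index=False):
        lo, hi = max(g.start - flank, 0), g.end + flank
        seg = segments[
            (segments["chrom"] == g.chrom)
            & (segments["end"] > lo)
            & (segments["start"] < hi)
        ]
        if len(seg) == 0:
            rows.append({"gene": g.name, "sample": sample, "median_cn": np.nan, "call": "uncallable"})
            continue
        vals = seg["seg_mean"].to_numpy(dtype=float)
        wts = (np.minimum(seg["end"], hi) - np.maximum(seg["start"], lo)).to_numpy(dtype=float)
        med = _weighted_median(vals, wts)
        if med > amp_threshold:
            call = "amplified"
        elif med < loss_threshold:
            call = "lost"
        else:
            call = "neutral"
        rows.append({"gene": g.name, "sample": sample, "median_cn": med, "call": call})
    return pd.DataFrame(rows)


def focal_concordance(tumor_calls: pd.DataFrame, pdx_calls: pd.DataFrame) -> pd.DataFrame:
    """Per-gene concordance of focal calls between a tumor and its PDX."""
    merged = tumor_calls.merge(pdx_calls, on="gene", suffixes=("_tumor", "_pdx"))
    merged["concordant"] = merged["call_tumor"] == merged["call_pdx"]
    return merged


def arm_level_events(
    profile: CopyNumberProfile,
    arm_bed: pd.DataFrame,
    gain_cn: float = ARM_GAIN_CN,
    loss_cn: float = ARM_LOSS_CN,
    fraction: float = ARM_FRACTION,
) -> pd.DataFrame:
    """Arm-level gain/loss calls from a windowed profile.

    An arm is gained when >= `fraction` of its unmasked windows have copy
    number >= `gain_cn`, lost when >= `fraction` have <= `loss_cn`, else
    neutral (gain checked first). Arms with no unmasked windows are
    uncallable.
    """
    if arm_bed is None or len(arm_bed) == 0:
        raise ValueError("arm definitions required")
    w = profile.windows
    rows = []
    for arm in arm_bed.itertuples(index=False):
        sel = (
            (w["chrom"] == arm.chrom).to_numpy()
            & (w["start"].to_numpy() < arm.end)
            & (w["end"].to_numpy() > arm.start)
            & ~profile.mask
        )
        cn = profile.copy_number[sel]
        if cn.size == 0:
            call = "uncallable"
        elif (cn >= gain_cn).mean() >= fraction:
            call = "gained"
        elif (cn <= loss_cn).mean() >= fraction:
            call = "lost"
        else:
            call = "neutral"
        rows.append({"arm": arm.name, "sample": profile.sample, "call": call,
                     "n_windows": int(cn.size)})
    return pd.DataFrame(rows)


def arm_recurrence(arm_calls: list[pd.DataFrame]) -> pd.DataFrame:
    """Count samples sharing each arm-level call across a cohort."""
    allc = pd.concat(arm_calls, ignore_index=True)
    rec = (
        allc[allc["call"].isin(["gained", "lost"])]
        .groupby(["arm", "call"])
        .size()
        .reset_index(name="n_samples")
    )
    return rec.sort_values(["arm", "call"]).reset_index(drop=True)
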