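"""Tumor and xenograft purity estimation.

Tumor cellularity is estimated from the mode of minor-allele frequencies
(MAFs) at heterozygous germline sites inside loss-of-heterozygosity (LOH)
regions: the tumor has lost one parental allele, so residual minor-allele
signal comes from contaminating normal cells. Under the copy-neutral LOH
model (two tumor copies of the retained allele) the expected MAF is
m = (1 - p) / 2, giving p = 1 - 2m. A hemizygous-deletion model
(one tumor copy), m = (1 - p) / (2 - p), is available behind a flag.

Xenograft purity is the fraction of sequencing reads classified as
human-specific by competitive graft/host alignment; all non-human-specific
classes (mouse-specific, both, neither, ambiguous) are removed before
downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pdxfidelity.stats import percent


@dataclass
class PurityEstimate:
    purity: float
    maf_mode: float
    n_sites: int
    model: str


def _histogram_mode(maf: np.ndarray, bin_width: float) -> float:
    """Peak of the MAF histogram refined around the peak bin.

    Bins tile [0, 0.5]. Degenerate case first: when every observation in
    the peak bin coincides, that exact value is the mode. Otherwise a
    Gaussian kernel density over the data in a window around the peak bin
    is maximized on a fine grid (the kernel bandwidth shrinks with sample
    size, so the mode estimate sharpens as sites accumulate); if the KDE
    is unavailable (near-degenerate data), parabolic interpolation over
    the peak bin and its neighbors is used instead.
    """
    n_bins = int(np.ceil(0.5 / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(maf, bins=edges)
    i = int(np.argmax(counts))
    in_peak = maf[(maf >= edges[i]) & (maf <= edges[i + 1])]
    if in_peak.size and np.allclose(in_peak, in_peak[0], atol=1e-12):
        return float(in_peak[0])
    lo = max(edges[i] - 5 * bin_width, 0.0)
    hi = min(edges[i + 1] + 5 * bin_width, 0.5)
    window = maf[(maf >= lo) & (maf <= hi)]
    try:
        from scipy.stats import gaussian_kde

        # weighted KDE over unique values: invariant to site order and to
        # duplicating the whole site list
        vals, cnts = np.unique(window, return_counts=True)
        kde = gaussian_kde(vals, weights=cnts)
        grid = np.linspace(lo, hi, 501)
        return float(grid[int(np.argmax(kde(grid)))])
    except (np.linalg.LinAlgError, ValueError):
        left = counts[i - 1] if i > 0 else 0
        right = counts[i + 1] if i < n_bins - 1 else 0
        peak = counts[i]
        denom = left - 2 * peak + right
        offset = 0.0 if denom == 0 else 0.5 * (left - right) / denom
        offset = float(np.clip(offset, -0.5, 0.5))
        return float(edges[i] + (0.5 + offset) * bin_width)


def estimate_purity_loh(
    sites: pd.DataFrame | np.ndarray,
    bin_width: float = 0.01,
    min_sites: int = 50,
    model: str = "copy_neutral",
) -> PurityEstimate:
    """Estimate tumor purity from the MAF mode in LOH regions.

    `sites` is either an array of MAFs or a frame with a `maf` column (or
    ref_count/alt_count pairs from which MAFs are derived); rows flagged
    `in_loh == False` are dropped. Purity is 1 - 2m (copy-neutral) or
    (1 - 2m) / (1 - m) (hemizygous deletion), clipped to (0, 1].
    """
    if isinstance(sites, pd.DataFrame):
        df = sites
        if "in_loh" in df.columns:
            df = df[df["in_loh"].astype(bool)]
        if "maf" in df.columns:
            maf = df["maf"].to_numpy(dtype=float)
        elif {"ref_count", "alt_count"} <= set(df.columns):
            ref = df["ref_count"].to_numpy(dtype=float)
            alt = df["alt_count"].to_numpy(dtype=float)
            total = ref + alt
            if (total <= 0).any():
                raise ValueError("site with zero total reads")
            maf = np.minimum(ref, alt) / total
        else:
            raise ValueError("sites frame needs a 'maf' or ref_count/alt_count columns")
    else:
        maf = np.asarray(sites, dtype=float)
    if maf.size < min_sites:
        raise ValueError(f"only {maf.size} LOH sites (need >= {min_sites})")
    if (maf < 0).any() or (maf > 0.5 + 1e-12).any():
        raise ValueError("MAF values must lie in [0, 0.5]")
    m = _histogram_mode(maf, bin_width)
    if model == "copy_neutral":
        p = 1.0 - 2.0 * m
    elif model == "hemizygous_deletion":
        # m = (1-p)/(2-p)  =>  p = (1 - 2m) / (1 - m)
        p = (1.0 - 2.0 * m) / (1.0 - m) if m < 1 else 0.0
    else:
        raise ValueError(f"unknown purity model {model!r}")
    p = float(np.clip(p, np.finfo(float).tiny, 1.0))
    return PurityEstimate(purity=p, maf_mode=m, n_sites=int(maf.size), model=model)


READ_CLASSES = ("human_specific", "mouse_specific", "both", "neither", "ambiguous")


def xenograft_read_purity(counts: dict[str, int] | pd.Series) -> dict:
    """Xenograft purity from graft/host read-classification counts.

    Purity = human-specific reads / all classified reads (the denominator
    includes the both/neither/ambiguous classes, all of which are removed
    before downstream analysis). Returns per-class percentages, the purity
    percentage, and a flag stating that only human-specific reads are
    retained downstream.
    """
    c = {k: int(counts.get(k, 0)) for k in READ_CLASSES}
    if any(v < 0 for v in c.values()):
        raise ValueError("negative read counts")
    total = sum(c.values())
    if total == 0:
        raise ValueError("zero total reads")
    pct = {k: percent(v, total) for k, v in c.items()}
    return {
        "counts": c,
        "total": total,
        "class_pct": pct,
        "purity_pct": pct["human_specific"],
        "purity": c["human_specific"] / total,
        "retained_downstream": "human_specific",
    }
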