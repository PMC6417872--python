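"""Somatic variant classification, retention/recovery, and VAF concordance
across matched tumor/PDX (and multi-passage) samples.

The central procedure: variants are called independently in tumor and PDX,
the union of events is re-interrogated in both samples from pileup counts,
and every (variant, sample) pair receives exactly one of five labels:

    detected               alt > 0, depth >= 20x, VAF >= 5%
    low_coverage           alt > 0, depth < 20x
    low_VAF                alt > 0, depth >= 20x, VAF < 5%
    undetected_low_coverage  alt = 0, depth < 20x
    undetected             alt = 0, depth >= 20x

A tumor variant is *retained* if independently called in the PDX too, and
*recovered* if absent from the PDX call set but supported by at least one
alt read on re-interrogation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from pdxfidelity.stats import percent, percent_truncated

DEPTH_THRESHOLD = 20
VAF_THRESHOLD = 0.05

CLASS_LABELS = (
    "detected",
    "low_coverage",
    "low_VAF",
    "undetected_low_coverage",
    "undetected",
)

_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class VariantObservation:
    """One somatic event observed in one sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str
    depth: int
    alt_reads: int
    called: bool = False  # present in this sample's independent call set

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_reads < 0:
            raise ValueError("negative read counts")
        if self.alt_reads > self.depth:
            raise ValueError("alt reads exceed depth")

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth if self.depth > 0 else 0.0


def classify_observation(
    obs: VariantObservation | None = None,
    depth_threshold: int = DEPTH_THRESHOLD,
    vaf_threshold: float = VAF_THRESHOLD,
    *,
    depth: int | None = None,
    alt_reads: int | None = None,
) -> str:
    """Assign the five-way class label to one observation.

    Accepts either a VariantObservation or raw depth/alt_reads counts.
    Threshold comparisons are inclusive (>= 20x, >= 5%). When alt reads
    are present but both depth and VAF fall below threshold (unreachable
    at the defaults, possible for other settings), insufficient coverage
    takes precedence and the label is low_coverage.
    """
    if obs is not None:
        depth, alt_reads = obs.depth, obs.alt_reads
    if depth is None or alt_reads is None:
        raise ValueError("provide an observation or depth and alt_reads")
    if depth < 0 or alt_reads < 0:
        raise ValueError("negative read counts")
    if alt_reads > depth:
        raise ValueError("alt reads exceed depth")
    if alt_reads == 0:
        return "undetected_low_coverage" if depth < depth_threshold else "undetected"
    vaf = alt_reads / depth
    if depth < depth_threshold:
        return "low_coverage"
    return "detected" if vaf >= vaf_threshold else "low_VAF"


def _classify_arrays(depth: np.ndarray, alt: np.ndarray, dt: int, vt: float) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    out = np.where(
        alt == 0,
        np.where(depth < dt, "undetected_low_coverage", "undetected"),
        np.where(depth < dt, "low_coverage", np.where(vaf >= vt, "detected", "low_VAF")),
    )
    return out.astype(object)


def _key_index(df: pd.DataFrame) -> pd.Index:
    return pd.MultiIndex.from_frame(df[_KEY])


def build_paired_table(
    tumor_calls: pd.DataFrame,
    pdx_calls: pd.DataFrame,
    tumor_pileup: pd.DataFrame,
    pdx_pileup: pd.DataFrame,
    depth_threshold: int = DEPTH_THRESHOLD,
    vaf_threshold: float = VAF_THRESHOLD,
) -> pd.DataFrame:
    """Union the two call sets and re-interrogate both samples.

    `tumor_calls`/`pdx_calls` carry the independently called variant keys
    (chrom, pos, ref, alt); the pileups must provide depth and alt_reads
    at every union position in the respective sample. Each row of the
    result carries both observations, both class labels, provenance
    (both / tumor_only / pdx_only at independent calling) and
    recovered-in-sample flags (>= 1 alt read at a position the sample's
    caller missed).
    """
    t_keys = set(map(tuple, tumor_calls[_KEY].itertuples(index=False)))
    p_keys = set(map(tuple, pdx_calls[_KEY].itertuples(index=False)))
    union = sorted(t_keys | p_keys)
    if not union:
        return _empty_paired_table()

    def pileup_map(pileup: pd.DataFrame, name: str) -> dict:
        m = {}
        for row in pileup.itertuples(index=False):
            m[(row.chrom, row.pos, row.ref, row.alt)] = (row.depth, row.alt_reads)
        missing = [k for k in union if k not in m]
        if missing:
            k = missing[0]
            raise ValueError(
                f"{name} pileup missing {len(missing)} union position(s), "
                f"first: {k[0]}:{k[1]} {k[2]}>{k[3]}"
            )
        return m

    t_map = pileup_map(tumor_pileup, "tumor")
    p_map = pileup_map(pdx_pileup, "pdx")

    rows = []
    for key in union:
        td, ta = t_map[key]
        pdp, pa = p_map[key]
        in_t, in_p = key in t_keys, key in p_keys
        provenance = "both" if (in_t and in_p) else ("tumor_only" if in_t else "pdx_only")
        rows.append(key + (td, ta, pdp, pa, in_t, in_p, provenance))
    table = pd.DataFrame(
        rows,
        columns=_KEY
        + [
            "tumor_depth",
            "tumor_alt",
            "pdx_depth",
            "pdx_alt",
            "called_in_tumor",
            "called_in_pdx",
            "provenance",
        ],
    )
    for role in ("tumor", "pdx"):
        depth = table[f"{role}_depth"].to_numpy()
        alt = table[f"{role}_alt"].to_numpy()
        table[f"{role}_vaf"] = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
        table[f"{role}_label"] = _classify_arrays(depth, alt, depth_threshold, vaf_threshold)
    table["recovered_in_pdx"] = ~table["called_in_pdx"] & (table["pdx_alt"] > 0)
    table["recovered_in_tumor"] = ~table["called_in_tumor"] & (table["tumor_alt"] > 0)
    return table


def _empty_paired_table() -> pd.DataFrame:
    cols = _KEY + [
        "tumor_depth", "tumor_alt", "pdx_depth", "pdx_alt",
        "called_in_tumor", "called_in_pdx", "provenance",
        "tumor_vaf", "tumor_label", "pdx_vaf", "pdx_label",
        "recovered_in_pdx", "recovered_in_tumor",
    ]
    return pd.DataFrame(columns=cols)


@dataclass
class RetentionMetrics:
    """Tumor-to-PDX retention summary for one pair."""

    total: int
    detected: int
    recovered: int
    pct_detected: float
    pct_recovered: float
    pct_shared: float
    rounding: str = "half_up"  # or "truncated"
    pdx_specific: int = 0
    r_squared: float | None = None
    slope: float | None = None
    intercept: float | None = None
    shared_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.detected <= self.total and 0 <= self.recovered <= self.total):
            raise ValueError("counts must be non-negative and <= total")
        if self.detected + self.recovered > self.total:
            raise ValueError("detected + recovered exceed total")
        self.shared_fraction = (
            (self.detected + self.recovered) / self.total if self.total else 0.0
        )


def retention_from_counts(
    total: int, detected: int, recovered: int, rounding: str = "half_up"
) -> RetentionMetrics:
    """Retention percentages from pre-tabulated counts.

    `rounding`: "half_up" reports one decimal, round-half-up; "truncated"
    reports truncated integers (the convention used for passage
    percentages).
    """
    if total <= 0:
        raise ValueError("empty table: total must be > 0")
    if rounding == "half_up":
        pd_, pr, ps = (
            percent(detected, total),
            percent(recovered, total),
            percent(detected + recovered, total),
        )
    elif rounding == "truncated":
        pd_, pr, ps = (
            percent_truncated(detected, total),
            percent_truncated(recovered, total),
            percent_truncated(detected + recovered, total),
        )
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return RetentionMetrics(total, detected, recovered, pd_, pr, ps, rounding)


def retention_summary(
    table: pd.DataFrame, rounding: str = "half_up", with_regression: bool = False
) -> RetentionMetrics:
    """Tumor-to-PDX retention from a paired table.

    detected = tumor-called variants independently called in the PDX;
    recovered = tumor-called variants accounted for only on
    re-interrogation (>= 1 PDX alt read); shared = their sum.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    tumor_called = table[table["called_in_tumor"]]
    total = len(tumor_called)
    if total == 0:
        raise ValueError("no tumor-called variants in table")
    detected = int(tumor_called["called_in_pdx"].sum())
    recovered = int(tumor_called["recovered_in_pdx"].sum())
    m = retention_from_counts(total, detected, recovered, rounding)
    m.pdx_specific = int((table["provenance"] == "pdx_only").sum())
    if with_regression:
        try:
            r2, slope, intercept, _ = vaf_concordance(table)
            m.r_squared, m.slope, m.intercept = r2, slope, intercept
        except ValueError:
            pass
    return m


def vaf_concordance(
    table: pd.DataFrame, min_depth: int = DEPTH_THRESHOLD
) -> tuple[float, float, float, int]:
    """OLS of PDX VAF on tumor VAF over variants shared between samples.

    Restricted to variants with alt reads in both samples and at least
    `min_depth` coverage in both. Returns (R^2, slope, intercept, n).
    """
    use = table[
        (table["tumor_alt"] > 0)
        & (table["pdx_alt"] > 0)
        & (table["tumor_depth"] >= min_depth)
        & (table["pdx_depth"] >= min_depth)
    ]
    if len(use) < 3:
        raise ValueError(f"only {len(use)} usable points (need >= 3)")
    x = use["tumor_vaf"].to_numpy(dtype=float)
    y = use["pdx_vaf"].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("tumor VAFs are constant; regression undefined")
    res = sps.linregress(x, y)
    return float(res.rvalue**2), float(res.slope), float(res.intercept), len(use)


def pdx_specific_report(
    table: pd.DataFrame,
    rna_pileup: pd.DataFrame | None = None,
    driver_genes: pd.DataFrame | None = None,
    vaf_threshold: float = VAF_THRESHOLD,
    depth_threshold: int = DEPTH_THRESHOLD,
) -> dict:
    """Characterize variants detected only in the PDX.

    expressed = >= 1 alt read in the PDX RNA pileup; low_vaf = PDX VAF
    <= 5% (the threshold is inclusive here, matching a "at or below the
    detection limit" reading); low_tumor_coverage = < 20x tumor depth.
    `driver_genes` is a BED-style frame (chrom/start/end/name, 0-based
    half-open) used to flag PDX-only events in driver genes.
    """
    only = table[table["provenance"] == "pdx_only"]
    n = len(only)
    report: dict = {"n_pdx_only": n}
    if rna_pileup is not None:
        rna = {}
        for row in rna_pileup.itertuples(index=False):
            rna[(row.chrom, row.pos, row.ref, row.alt)] = row.alt_reads
        expressed = 0
        for key in map(tuple, only[_KEY].itertuples(index=False)):
            if key not in rna:
                raise ValueError(f"RNA pileup missing PDX-only position {key[0]}:{key[1]}")
            if rna[key] > 0:
                expressed += 1
        report["n_expressed"] = expressed
        report["pct_expressed"] = percent(expressed, n) if n else 0.0
    n_low_vaf = int((only["pdx_vaf"] <= vaf_threshold).sum())
    n_low_cov = int((only["tumor_depth"] < depth_threshold).sum())
    report["n_low_vaf"] = n_low_vaf
    report["n_low_tumor_coverage"] = n_low_cov
    report["pct_low_vaf"] = percent(n_low_vaf, n) if n else 0.0
    report["pct_low_tumor_coverage"] = percent(n_low_cov, n) if n else 0.0
    if driver_genes is not None:
        annotated = annotate_genes(only, driver_genes)
        report["driver_overlaps"] = sorted(
            annotated.loc[annotated["gene"].notna(), "gene"].unique()
        )
    return report


def annotate_genes(table: pd.DataFrame, gene_bed: pd.DataFrame) -> pd.DataFrame:
    """Attach a `gene` column by interval overlap (positions are 0-based)."""
    required = {"chrom", "start", "end", "name"}
    if not required <= set(gene_bed.columns):
        raise ValueError(f"gene BED must have columns {sorted(required)}")
    out = table.copy()
    genes = pd.Series(pd.NA, index=out.index, dtype=object)
    for g in gene_bed.itertuples(index=False):
        hit = (out["chrom"] == g.chrom) & (out["pos"] >= g.start) & (out["pos"] < g.end)
        genes[hit] = g.name
    out["gene"] = genes
    return out


def driver_conservation(table: pd.DataFrame, driver_bed: pd.DataFrame) -> dict:
    """Per-driver-gene mutation counts and pair-level conservation.

    A pair is conserved when every tumor-called driver mutation is either
    independently called or recovered in the PDX.
    """
    annotated = annotate_genes(table, driver_bed)
    in_driver = annotated[annotated["gene"].notna()]
    per_gene = []
    for gene, grp in in_driver.groupby("gene"):
        n_tumor = int(grp["called_in_tumor"].sum())
        n_pdx = int(grp["called_in_pdx"].sum())
        n_shared = int((grp["called_in_tumor"] & grp["called_in_pdx"]).sum())
        per_gene.append(
            {"gene": gene, "n_tumor": n_tumor, "n_pdx": n_pdx, "n_shared": n_shared}
        )
    tumor_drv = in_driver[in_driver["called_in_tumor"]]
    conserved = bool(
        (tumor_drv["called_in_pdx"] | tumor_drv["recovered_in_pdx"]).all()
    )
    lost = tumor_drv[~(tumor_drv["called_in_pdx"] | tumor_drv["recovered_in_pdx"])]
    return {
        "per_gene": pd.DataFrame(per_gene, columns=["gene", "n_tumor", "n_pdx", "n_shared"]),
        "conserved": conserved,
        "lost_driver_mutations": lost.reset_index(drop=True),
    }


def passage_stability(
    primary_calls: pd.DataFrame,
    p0_calls: pd.DataFrame,
    p2_calls: dict[str, pd.DataFrame],
    pileups: dict[str, pd.DataFrame],
    depth_threshold: int = DEPTH_THRESHOLD,
    vaf_threshold: float = VAF_THRESHOLD,
) -> dict:
    """Variant retention across serial passages (primary -> P0 -> P2s).

    All samples must be re-interrogated at the union of calls (`pileups`
    keyed "primary", "p0", and each P2 name). Retention percentages are
    reported as truncated integers. Returns retention of primary variants
    in P0, retention of P0-confirmed variants in each P2, and a table of
    variants private to the P2 generation with per-replicate VAFs and a
    shared-across-all-P2s flag.
    """
    if not p2_calls:
        raise ValueError("empty P2 list")
    call_sets = {"primary": primary_calls, "p0": p0_calls, **p2_calls}
    union = sorted(
        set().union(*(map(tuple, c[_KEY].itertuples(index=False)) for c in call_sets.values()))
    )
    labels: dict[str, dict] = {}
    vafs: dict[str, dict] = {}
    for name in call_sets:
        if name not in pileups:
            raise ValueError(f"missing pileup for sample {name!r}")
        m = {}
        for row in pileups[name].itertuples(index=False):
            m[(row.chrom, row.pos, row.ref, row.alt)] = (row.depth, row.alt_reads)
        missing = [k for k in union if k not in m]
        if missing:
            raise ValueError(f"{name} pileup missing position {missing[0]}")
        labels[name] = {
            k: classify_observation(
                depth=m[k][0], alt_reads=m[k][1],
                depth_threshold=depth_threshold, vaf_threshold=vaf_threshold,
            )
            for k in union
        }
        vafs[name] = {k: (m[k][1] / m[k][0] if m[k][0] > 0 else 0.0) for k in union}

    primary_keys = sorted(map(tuple, primary_calls[_KEY].itertuples(index=False)))
    n_primary = len(primary_keys)
    p0_detected = [k for k in primary_keys if labels["p0"][k] == "detected"]
    result = {
        "n_primary": n_primary,
        "n_detected_p0": len(p0_detected),
        "pct_detected_p0": percent_truncated(len(p0_detected), n_primary),
        "p2": {},
    }
    for name in p2_calls:
        det = [k for k in p0_detected if labels[name][k] == "detected"]
        result["p2"][name] = {
            "n_confirmed": len(det),
            "pct_confirmed": percent_truncated(len(det), len(p0_detected))
            if p0_detected
            else 0,
        }

    p2_keys = set().union(
        *(map(tuple, c[_KEY].itertuples(index=False)) for c in p2_calls.values())
    )
    private = []
    for k in sorted(p2_keys):
        if labels["primary"][k] == "detected" or labels["p0"][k] == "detected":
            continue
        row = dict(zip(_KEY, k))
        shared = True
        for name in p2_calls:
            row[f"{name}_vaf"] = vafs[name][k]
            if labels[name][k] != "detected":
                shared = False
        row["shared_all_p2"] = shared
        private.append(row)
    result["p2_private"] = pd.DataFrame(private)
    return result
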