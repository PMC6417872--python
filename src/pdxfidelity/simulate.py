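"""Synthetic paired tumor/PDX/normal cohort generator.

Emulates the data-generating process the downstream analyses assume: a
subclonal clone tree with cancer-cell fractions (CCFs), tumor purity
diluting variant allele fractions, an engraftment bottleneck resampling
clone fractions into the xenograft, finite overdispersed sequencing depth,
paired copy-number profiles, and expression with a stromal-infiltrate
admixture on top of molecular-subtype centroids.

Coordinates are 0-based half-open internally; VCF output is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

SUBTYPES = ("atypical", "basal", "classical", "mesenchymal")

# TCGA-confirmed HNSCC subtype prevalences: atypical 24%, basal 31%,
# classical 18%, mesenchymal 27%
SUBTYPE_MIX = {"atypical": 0.24, "basal": 0.31, "classical": 0.18, "mesenchymal": 0.27}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Clone:
    clone_id: str
    ccf: float  # cancer-cell fraction in the tumor, (0, 1]
    parent: str | None = None


@dataclass
class CloneArchitecture:
    """Clone tree with per-clone variant counts and private CN events.

    `cn_events` maps clone_id to (chrom, start, end, absolute_copy_number)
    tuples; events are private to the clone and inherited by its
    descendants.
    """

    clones: list[Clone]
    variants_per_clone: int
    cn_events: dict[str, list[tuple[str, int, int, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError("empty architecture: at least one clone required")
        if self.variants_per_clone < 1:
            raise ValueError("variants_per_clone must be >= 1")
        by_id = {c.clone_id: c for c in self.clones}
        if len(by_id) != len(self.clones):
            raise ValueError("duplicate clone ids")
        roots = [c for c in self.clones if c.parent is None]
        if len(roots) != 1 or abs(roots[0].ccf - 1.0) > 1e-9:
            raise ValueError("exactly one founding clone with CCF = 1 required")
        for c in self.clones:
            if not 0 < c.ccf <= 1:
                raise ValueError(f"clone {c.clone_id}: CCF must be in (0, 1]")
            if c.parent is not None:
                if c.parent not in by_id:
                    raise ValueError(f"clone {c.clone_id}: unknown parent {c.parent}")
                if c.ccf > by_id[c.parent].ccf + 1e-9:
                    raise ValueError(
                        f"clone {c.clone_id}: CCF exceeds parent {c.parent}"
                    )
        for cid, events in self.cn_events.items():
            if cid not in by_id:
                raise ValueError(f"CN events for unknown clone {cid}")
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for chrom, start, end, cn in events:
                if start >= end or cn < 0:
                    raise ValueError(f"invalid CN event {(chrom, start, end, cn)}")
                by_chrom.setdefault(chrom, []).append((start, end))
            for chrom, ivals in by_chrom.items():
                ivals.sort()
                for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                    if s2 < e1:
                        raise ValueError(
                            f"overlapping CN events within clone {cid} on {chrom}"
                        )

    @property
    def clone_ids(self) -> list[str]:
        return [c.clone_id for c in self.clones]

    def children(self, clone_id: str) -> list[Clone]:
        return [c for c in self.clones if c.parent == clone_id]

    def ancestors_and_self(self, clone_id: str) -> list[str]:
        by_id = {c.clone_id: c for c in self.clones}
        out = [clone_id]
        cur = by_id[clone_id]
        while cur.parent is not None:
            out.append(cur.parent)
            cur = by_id[cur.parent]
        return out

    def subtree(self, clone_id: str) -> list[str]:
        out = [clone_id]
        stack = [clone_id]
        while stack:
            cid = stack.pop()
            for child in self.children(cid):
                out.append(child.clone_id)
                stack.append(child.clone_id)
        return out

    def population_fractions(self) -> dict[str, float]:
        """Fraction of cancer cells whose most-derived clone is each clone.

        f_c = CCF_c - sum of children CCFs; must be non-negative for the
        tree to describe a valid cell population.
        """
        fracs = {}
        for c in self.clones:
            f = c.ccf - sum(ch.ccf for ch in self.children(c.clone_id))
            if f < -1e-9:
                raise ValueError(
                    f"clone {c.clone_id}: children CCFs exceed the clone's own CCF"
                )
            fracs[c.clone_id] = max(f, 0.0)
        return fracs

    def clone_copy_number(self, clone_id: str, chrom: str, pos: int) -> float:
        """Total copy number at a position in cells of `clone_id` (inherits
        ancestral events; diploid background)."""
        for anc in self.ancestors_and_self(clone_id):
            for c2, s, e, cn in self.cn_events.get(anc, []):
                if c2 == chrom and s <= pos < e:
                    return cn
        return 2.0


@dataclass
class SimulationConfig:
    """Cohort-level generative parameters.

    Depth is negative-binomial (mean/dispersion) to mimic the
    overdispersion of capture sequencing; detection thresholds mirror the
    analysis defaults (20x depth, 5% VAF). The toy genome keeps runtimes
    small while leaving room for several segments per chromosome.
    """

    n_patients: int = 16
    tumor_purity: float = 0.8
    pdx_human_fraction: float = 0.95
    depth_mean: float = 80.0
    depth_dispersion: float = 3.0
    bottleneck: int = 100_000
    vaf_threshold: float = 0.05
    depth_threshold: int = 20
    normal_error_rate: float = 0.001
    genome: dict[str, int] = field(default_factory=lambda: {"chr1": 50_000_000, "chr2": 50_000_000})
    segment_noise_sd: float = 0.05
    stromal_effect: float = 2.0
    mesenchymal_caf_weight: float = 1.0
    expression_noise_sd: float = 0.25
    patient_effect_sd: float = 0.5
    centroid_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tumor_purity", "pdx_human_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if self.bottleneck < 1:
            raise ValueError("bottleneck size must be >= 1")
        if not 0 < self.vaf_threshold < 1:
            raise ValueError("vaf_threshold must be in (0, 1)")
        if self.normal_error_rate < 0:
            raise ValueError("normal_error_rate must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _draw_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    if dispersion <= 0 or np.isinf(dispersion):
        return np.full(n, int(round(mean)))
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def bottleneck_fractions(
    arch: CloneArchitecture, size: int, rng: np.random.Generator
) -> dict[str, float]:
    """Resample clone population fractions through a founding-cell bottleneck."""
    if size < 1:
        raise ValueError("bottleneck size must be >= 1")
    fracs = arch.population_fractions()
    ids = arch.clone_ids
    probs = np.array([fracs[c] for c in ids])
    probs = probs / probs.sum()
    counts = rng.multinomial(size, probs)
    return {c: counts[i] / size for i, c in enumerate(ids)}


def _ccf_from_fractions(arch: CloneArchitecture, fracs: dict[str, float]) -> dict[str, float]:
    return {c: sum(fracs[s] for s in arch.subtree(c)) for c in arch.clone_ids}


def simulate_paired_variants(
    arch: CloneArchitecture,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    pdx_fractions: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate read-count observations for one tumor/PDX/normal trio.

    Returns (observations, ground_truth). Observations carry per-sample
    depth and alt-read counts for every simulated somatic variant; ground
    truth records the clone, true tumor and PDX CCFs, expected VAFs, and
    whether the clone survived engraftment.

    The expected VAF in a sample with cancer-cell fraction `q` (tumor
    purity, or PDX human-cell fraction) is
    q * CCF * 1 / (q * <local copy number over cancer cells> + (1-q) * 2),
    i.e. one variant copy against the population-averaged locus ploidy.
    """
    if rng is None:
        rng = config.rng()
    if pdx_fractions is None:
        pdx_fractions = bottleneck_fractions(arch, config.bottleneck, rng)
    tumor_fracs = arch.population_fractions()
    tumor_ccf = {c.clone_id: c.ccf for c in arch.clones}
    pdx_ccf = _ccf_from_fractions(arch, pdx_fractions)

    chroms = list(config.genome)
    rows = []
    for clone in arch.clones:
        for _ in range(arch.variants_per_clone):
            ci = rng.integers(len(chroms))
            chrom = chroms[ci]
            pos = int(rng.integers(config.genome[chrom]))
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            rows.append((chrom, pos, str(ref), str(alt), clone.clone_id))
    truth = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "clone"])
    truth = truth.drop_duplicates(["chrom", "pos"]).reset_index(drop=True)

    def expected_vaf(row, ccf_map, fracs, q):
        local = sum(
            fracs[c] * arch.clone_copy_number(c, row.chrom, row.pos)
            for c in arch.clone_ids
        )
        denom = q * local + (1 - q) * 2.0
        if denom <= 0:
            return 0.0
        return q * ccf_map[row.clone] / denom

    truth["ccf_tumor"] = truth["clone"].map(tumor_ccf)
    truth["ccf_pdx"] = truth["clone"].map(pdx_ccf)
    truth["clone_survived"] = truth["ccf_pdx"] > 0
    truth["expected_vaf_tumor"] = [
        expected_vaf(r, tumor_ccf, tumor_fracs, config.tumor_purity)
        for r in truth.itertuples()
    ]
    truth["expected_vaf_pdx"] = [
        expected_vaf(r, pdx_ccf, pdx_fractions, config.pdx_human_fraction)
        for r in truth.itertuples()
    ]

    n = len(truth)
    obs = truth[["chrom", "pos", "ref", "alt", "clone"]].copy()
    for role, ev in (
        ("tumor", truth["expected_vaf_tumor"].to_numpy()),
        ("pdx", truth["expected_vaf_pdx"].to_numpy()),
        ("normal", np.full(n, config.normal_error_rate)),
    ):
        depth = _draw_depths(rng, n, config.depth_mean, config.depth_dispersion)
        alt = rng.binomial(depth, np.clip(ev, 0, 1))
        obs[f"{role}_depth"] = depth
        obs[f"{role}_alt"] = alt
    return obs, truth


def genome_segments(
    arch: CloneArchitecture,
    config: SimulationConfig,
    fracs: dict[str, float],
    cancer_fraction: float,
    rng: np.random.Generator,
    sample: str,
) -> pd.DataFrame:
    """Observed SEG table: clone-CN mixture diluted by normal diploid cells."""
    rows = []
    for chrom, length in config.genome.items():
        cuts = {0, length}
        for events in arch.cn_events.values():
            for c2, s, e, _ in events:
                if c2 == chrom:
                    cuts.update((min(s, length), min(e, length)))
        bounds = sorted(cuts)
        for s, e in zip(bounds, bounds[1:]):
            mid = (s + e) // 2
            mix = sum(
                fracs[c] * arch.clone_copy_number(c, chrom, mid)
                for c in arch.clone_ids
            )
            mean = cancer_fraction * mix + (1 - cancer_fraction) * 2.0
            if config.segment_noise_sd > 0:
                mean = max(mean + rng.normal(0, config.segment_noise_sd), 0.0)
            rows.append((sample, chrom, s, e, mean))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "seg_mean"])


def simulate_paired_segments(
    arch: CloneArchitecture,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    pdx_fractions: dict[str, float] | None = None,
    sample_prefix: str = "patient",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tumor and PDX SEG tables from one clone architecture.

    PDX clone fractions default to a fresh bottleneck draw; pass the
    fractions from `simulate_paired_variants` for a coherent trio.
    """
    if rng is None:
        rng = config.rng()
    if pdx_fractions is None:
        pdx_fractions = bottleneck_fractions(arch, config.bottleneck, rng)
    tumor = genome_segments(
        arch, config, arch.population_fractions(), config.tumor_purity, rng,
        f"{sample_prefix}_tumor",
    )
    pdx = genome_segments(
        arch, config, pdx_fractions, config.pdx_human_fraction, rng,
        f"{sample_prefix}_pdx",
    )
    return tumor, pdx


def make_centroids(
    signature_genes: Sequence[str],
    scale: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Deterministic subtype centroids over signature genes (log2 scale).

    Each subtype gets an independent Gaussian centroid; `scale` sets the
    inter-centroid separation relative to unit expression noise.
    """
    rng = np.random.default_rng(seed)
    data = {s: rng.normal(0, scale, len(signature_genes)) for s in SUBTYPES}
    return pd.DataFrame(data, index=list(signature_genes))


def simulate_expression(
    config: SimulationConfig,
    subtype_labels: Sequence[str],
    purities: Sequence[float],
    centroids: pd.DataFrame,
    caf_genes: Sequence[str] = (),
    rng: np.random.Generator | None = None,
    patient_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired tumor/PDX expression with a stromal-infiltrate admixture.

    In log2 space each sample is: subtype centroid + shared patient effect
    (the tumor-intrinsic component, identical in matched tumor and PDX)
    + stromal vector x (1 - purity) for tumors (xenografts carry
    essentially no human stroma) + i.i.d. Gaussian noise. The mesenchymal
    subtype's intrinsic component additionally carries the stromal vector
    scaled by `mesenchymal_caf_weight`, emulating the CAF-driven nature of
    that expression signature. Values are emitted on the linear
    (FPKM-like) scale, 2**x.

    Returns (matrix genes x samples, sample metadata).
    """
    if rng is None:
        rng = config.rng()
    labels = list(subtype_labels)
    purities = list(purities)
    if len(labels) != len(purities):
        raise ValueError("labels and purities must have equal length")
    unknown = set(labels) - set(centroids.columns)
    if unknown:
        raise ValueError(f"unknown subtype label(s): {sorted(unknown)}")
    if patient_ids is None:
        patient_ids = [f"patient{i + 1}" for i in range(len(labels))]

    genes = centroids.index
    stromal = pd.Series(0.0, index=genes)
    caf_in = [g for g in caf_genes if g in genes]
    stromal[caf_in] = config.stromal_effect

    cols, meta = {}, []
    for pid, label, purity in zip(patient_ids, labels, purities):
        intrinsic = centroids[label] + rng.normal(0, config.patient_effect_sd, len(genes))
        if label == "mesenchymal":
            intrinsic = intrinsic + config.mesenchymal_caf_weight * stromal
        for role, stromal_w in (("tumor", 1.0 - purity), ("pdx", 0.0)):
            noise = (
                rng.normal(0, config.expression_noise_sd, len(genes))
                if config.expression_noise_sd > 0
                else 0.0
            )
            cols[f"{pid}_{role}"] = intrinsic + stromal_w * stromal + noise
            meta.append({"sample": f"{pid}_{role}", "patient": pid, "role": role,
                         "subtype": label, "purity": purity})
    log_mat = pd.DataFrame(cols, index=genes)
    return np.power(2.0, log_mat), pd.DataFrame(meta).set_index("sample")


def simulate_loh_sites(
    purity: float,
    depth_mean: float,
    n_sites: int,
    rng: np.random.Generator,
    depth_dispersion: float = 3.0,
) -> pd.DataFrame:
    """Heterozygous germline sites inside copy-neutral LOH regions.

    The tumor keeps two copies of one parental allele; residual normal
    cells contribute the lost allele, so the expected minor-allele
    fraction is (1 - purity) / 2.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    depth = np.maximum(_draw_depths(rng, n_sites, depth_mean, depth_dispersion), 1)
    maf_expected = (1 - purity) / 2.0
    minor = rng.binomial(depth, maf_expected)
    maf = np.minimum(minor / depth, 1 - minor / depth)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_sites + 1) * 1000,
            "ref_count": depth - minor,
            "alt_count": minor,
            "maf": maf,
            "in_loh": True,
        }
    )


def random_architecture(
    rng: np.random.Generator,
    config: SimulationConfig,
    n_subclones: int = 2,
    variants_per_clone: int = 60,
    n_cn_events: int = 6,
) -> CloneArchitecture:
    """A random linear clone tree with founder CN events.

    CN events are attached to the founding clone so tumor and PDX share
    them (the patient-specific copy-number fingerprint); subclone CCFs
    descend geometrically from the founder.
    """
    clones = [Clone("founder", 1.0, None)]
    parent, ccf = "founder", 1.0
    for i in range(n_subclones):
        ccf = ccf * rng.uniform(0.2, 0.6)
        cid = f"sub{i + 1}"
        clones.append(Clone(cid, round(ccf, 4), parent))
        parent = cid
    events = []
    chroms = list(config.genome)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for _ in range(n_cn_events):
        for _attempt in range(20):
            chrom = chroms[rng.integers(len(chroms))]
            length = int(rng.integers(2_000_000, 10_000_000))
            start = int(rng.integers(max(config.genome[chrom] - length, 1)))
            end = start + length
            if all(e <= start or end <= s for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                cn = float(rng.choice([0.0, 1.0, 3.0, 4.0, 5.0]))
                events.append((chrom, start, end, cn))
                break
    return CloneArchitecture(
        clones=clones,
        variants_per_clone=variants_per_clone,
        cn_events={"founder": events},
    )


def simulate_cohort(
    config: SimulationConfig,
    purities: Sequence[float] | None = None,
    n_subclones: int = 2,
    variants_per_clone: int = 60,
    signature_genes: Sequence[str] | None = None,
    caf_genes: Sequence[str] | None = None,
) -> dict:
    """Full synthetic cohort: per-patient variant trios, SEG tables,
    expression, subtype labels and all ground truth.

    Returns a dict with keys: patients (list of per-patient dicts with
    observations/truth/segments), expression, expression_meta, centroids,
    signature_genes, caf_genes, purities, subtypes, config.
    """
    rng = config.rng()
    n = config.n_patients
    if purities is None:
        purities = np.round(rng.uniform(0.4, 0.95, n), 3).tolist()
    purities = list(purities)
    if len(purities) != n:
        raise ValueError("purities length must equal n_patients")

    if signature_genes is None:
        signature_genes = [f"SIG{i:04d}" for i in range(400)]
    if caf_genes is None:
        caf_genes = [f"CAF{i:04d}" for i in range(120)]
    all_genes = list(signature_genes) + [g for g in caf_genes if g not in set(signature_genes)]
    centroids = make_centroids(all_genes, scale=config.centroid_scale, seed=config.seed)

    subtype_names = list(SUBTYPE_MIX)
    subtypes = [
        subtype_names[i] for i in rng.choice(
            len(subtype_names), size=n, p=list(SUBTYPE_MIX.values())
        )
    ]

    patients = []
    for i in range(n):
        pid = f"patient{i + 1}"
        pconf = replace(config, tumor_purity=purities[i])
        arch = random_architecture(
            rng, pconf, n_subclones=n_subclones, variants_per_clone=variants_per_clone
        )
        pdx_fracs = bottleneck_fractions(arch, pconf.bottleneck, rng)
        obs, truth = simulate_paired_variants(arch, pconf, rng, pdx_fractions=pdx_fracs)
        seg_t, seg_p = simulate_paired_segments(
            arch, pconf, rng, pdx_fractions=pdx_fracs, sample_prefix=pid
        )
        patients.append(
            {
                "patient": pid,
                "purity": purities[i],
                "architecture": arch,
                "pdx_fractions": pdx_fracs,
                "observations": obs,
                "truth": truth,
                "segments_tumor": seg_t,
                "segments_pdx": seg_p,
            }
        )

    expr, meta = simulate_expression(
        config, subtypes, purities, centroids, caf_genes=caf_genes, rng=rng,
        patient_ids=[p["patient"] for p in patients],
    )
    return {
        "patients": patients,
        "expression": expr,
        "expression_meta": meta,
        "centroids": centroids,
        "signature_genes": list(signature_genes),
        "caf_genes": list(caf_genes),
        "purities": purities,
        "subtypes": subtypes,
        "config": config,
    }


def observations_to_calls(
    obs: pd.DataFrame, role: str, config: SimulationConfig
) -> pd.DataFrame:
    """Independent call set for one sample: variants passing the depth,
    VAF and alt-read detection rule in that sample."""
    depth = obs[f"{role}_depth"].to_numpy()
    alt = obs[f"{role}_alt"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    keep = (alt > 0) & (depth >= config.depth_threshold) & (vaf >= config.vaf_threshold)
    return obs.loc[keep, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)


def observations_to_pileup(obs: pd.DataFrame, role: str, sample: str) -> pd.DataFrame:
    out = obs[["chrom", "pos", "ref", "alt"]].copy()
    out.insert(0, "sample", sample)
    out["depth"] = obs[f"{role}_depth"].to_numpy()
    out["alt_reads"] = obs[f"{role}_alt"].to_numpy()
    return out
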