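"""HNSCC molecular-subtype classification and CAF-signature scoring.

A random-forest classifier over a 638-gene signature assigns each sample
one of the four HNSCC expression subtypes (atypical, basal, classical,
mesenchymal), with vote fractions as class probabilities. Expression is
log2-transformed (for linear-scale input) and gene-median-centered (GMC)
per dataset — the sole cross-platform harmonization. The cancer-associated
fibroblast (CAF) signature score is the median GMC value over 412 CAF
genes, expected to be elevated in mesenchymal-classified samples because
that subtype's signature is driven largely by stromal infiltrate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from pdxfidelity.stats import rank_sum_test

SUBTYPE_LABELS = ("atypical", "basal", "classical", "mesenchymal")
MARGINAL_THRESHOLD = 0.4
CAF_COVERAGE_FLOOR = 0.8


def gene_median_normalize(matrix: pd.DataFrame, log2: bool = False) -> pd.DataFrame:
    """Subtract each gene's median across samples (GMC).

    `log2=True` first applies log2(x+1) for linear-scale input. Output row
    medians are exactly 0; idempotent on already-centered data.
    """
    if matrix.isna().all(axis=1).any():
        bad = matrix.index[matrix.isna().all(axis=1)].tolist()
        raise ValueError(f"all-missing gene row(s): {bad[:5]}")
    m = np.log2(matrix + 1.0) if log2 else matrix
    return m.sub(m.median(axis=1), axis=0)


@dataclass
class SubtypeModel:
    """Fitted subtype classifier with its signature and provenance."""

    signature: list[str]
    labels: list[str]
    forest: RandomForestClassifier
    seed: int
    n_trees: int
    training_accuracy: float
    oob_accuracy: float
    confusion: pd.DataFrame
    missing_in_training: list[str] = field(default_factory=list)


def _signature_features(
    matrix: pd.DataFrame, signature: list[str], max_missing: float = 0.2
) -> tuple[pd.DataFrame, list[str]]:
    """Signature-gene rows in signature order; absent genes imputed as 0
    (the centered null). Refuses if more than `max_missing` are absent."""
    missing = [g for g in signature if g not in matrix.index]
    if len(missing) > max_missing * len(signature):
        raise ValueError(
            f"{len(missing)}/{len(signature)} signature genes missing (> {max_missing:.0%})"
        )
    feats = matrix.reindex(signature).fillna(0.0)
    return feats, missing


def train_subtype_model(
    matrix: pd.DataFrame,
    labels: pd.Series | dict[str, str],
    signature: list[str],
    seed: int,
    n_trees: int = 500,
) -> SubtypeModel:
    """Fit the random forest on gene-median-centered signature expression.

    `matrix` is genes x samples, already GMC; `labels` maps sample id to
    subtype. Deterministic given `seed`; reports training accuracy,
    out-of-bag accuracy, and the per-class confusion of OOB predictions.
    """
    labels = pd.Series(labels)
    samples = [s for s in matrix.columns if s in labels.index]
    if len(samples) < len(matrix.columns):
        raise ValueError("labels missing for some training samples")
    y = labels[samples]
    counts = y.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"class(es) with < 2 training samples: {small.index.tolist()}")
    feats, missing = _signature_features(matrix[samples], list(signature))
    x = feats.T.to_numpy(dtype=float)
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, oob_score=True, n_jobs=1
    )
    forest.fit(x, y.to_numpy())
    train_acc = float((forest.predict(x) == y.to_numpy()).mean())
    oob_pred = forest.classes_[np.argmax(forest.oob_decision_function_, axis=1)]
    confusion = pd.crosstab(
        pd.Series(y.to_numpy(), name="true"), pd.Series(oob_pred, name="oob_predicted")
    )
    return SubtypeModel(
        signature=list(signature),
        labels=list(forest.classes_),
        forest=forest,
        seed=seed,
        n_trees=n_trees,
        training_accuracy=train_acc,
        oob_accuracy=float(forest.oob_score_),
        confusion=confusion,
        missing_in_training=missing,
    )


def predict_subtype(
    model: SubtypeModel,
    matrix: pd.DataFrame,
    marginal_threshold: float = MARGINAL_THRESHOLD,
) -> pd.DataFrame:
    """Per-sample subtype call with class probabilities.

    `matrix` must be gene-median-centered with the training convention.
    Probabilities are ensemble vote fractions; a call whose top
    probability falls below `marginal_threshold` is flagged marginal.
    """
    present = [g for g in model.signature if g in matrix.index]
    if not present:
        raise ValueError("no signature genes present in matrix")
    feats, _ = _signature_features(matrix, model.signature)
    proba = model.forest.predict_proba(feats.T.to_numpy(dtype=float))
    classes = list(model.forest.classes_)
    out = pd.DataFrame(proba, index=matrix.columns, columns=classes)
    out["label"] = out[classes].idxmax(axis=1)
    out["max_probability"] = out[classes].max(axis=1)
    out["marginal"] = out["max_probability"] < marginal_threshold
    return out


def save_model_metadata(model: SubtypeModel, path: str) -> None:
    """Serialize model provenance (version, seed, gene list, accuracies)."""
    meta = {
        "format_version": 1,
        "seed": model.seed,
        "n_trees": model.n_trees,
        "labels": model.labels,
        "training_accuracy": model.training_accuracy,
        "oob_accuracy": model.oob_accuracy,
        "signature": model.signature,
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1)


def caf_signature_score(
    matrix: pd.DataFrame,
    caf_genes: list[str],
    subtype_labels: pd.Series | dict[str, str] | None = None,
    coverage_floor: float = CAF_COVERAGE_FLOOR,
) -> dict:
    """Median GMC value over the CAF genes per sample.

    Requires at least `coverage_floor` of the CAF genes present (missing
    genes are named in the error, never silently dropped). When subtype
    labels are supplied, one-sided rank-sum tests compare the mesenchymal
    group against each other subtype.
    """
    present = [g for g in caf_genes if g in matrix.index]
    missing = [g for g in caf_genes if g not in matrix.index]
    if len(present) < coverage_floor * len(caf_genes):
        raise ValueError(
            f"CAF coverage {len(present)}/{len(caf_genes)} below floor "
            f"{coverage_floor:.0%}; missing e.g. {missing[:10]}"
        )
    scores = matrix.loc[present].median(axis=0)
    result: dict = {"scores": scores, "missing_genes": missing}
    if subtype_labels is not None:
        labels = pd.Series(subtype_labels)
        mes = scores[[s for s in scores.index if labels.get(s) == "mesenchymal"]]
        comparisons = {}
        for other in ("atypical", "basal", "classical"):
            grp = scores[[s for s in scores.index if labels.get(s) == other]]
            if len(mes) and len(grp):
                comparisons[other] = rank_sum_test(mes.to_numpy(), grp.to_numpy())
        result["mesenchymal_vs"] = comparisons
    return result
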