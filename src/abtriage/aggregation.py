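"""Isolation-forest anomaly scoring of surface feature vectors.

A coarse structure is summarised as a fixed 20-feature vector (per property:
mean, sd and max of the centroid values on their thresholding scale, plus the
largest-patch size and the patch count). An isolation forest trained on a
reference panel assigns each candidate an anomaly score in (0, 1] — the
standard 2^(-E[h(x)]/c(psi)) scale, higher = more anomalous = worse — and a
candidate is flagged when its score lies more than 2 standard deviations
above the reference-panel mean.

The fitted forest is persisted as JSON (tree arrays plus schema version);
scoring always runs through the package's own tree traversal so that a
save/load round-trip reproduces scores exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import IsolationForest

from .surface import PROPERTY_NAMES, CoarseStructure, Patch, property_magnitude

SCHEMA_VERSION = 1

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{prop}_{stat}"
    for prop in PROPERTY_NAMES
    for stat in ("mean", "sd", "max", "largest_patch", "patch_count")
)

N_FEATURES = len(FEATURE_NAMES)


@dataclass(frozen=True)
class SurfaceFeatureVector:
    panel_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {len(self.values)}")


@dataclass(frozen=True)
class AggregationScore:
    score: float
    z: float
    flagged: bool


def featurize(structure: CoarseStructure,
              patches_by_property: dict[str, Sequence[Patch]],
              panel_id: str = "") -> SurfaceFeatureVector:
    """Deterministic 20-feature summary of a structure's centroid landscape."""
    if structure.centroids is None:
        raise ValueError("structure lacks centroids")
    values: list[float] = []
    for prop in PROPERTY_NAMES:
        mags = np.array([property_magnitude(prop, c.property_value(prop))
                         for c in structure.centroids])
        patches = patches_by_property.get(prop, [])
        largest = max((p.n_member_residues for p in patches), default=0)
        values.extend([float(mags.mean()), float(mags.std()), float(mags.max()),
                       float(largest), float(len(patches))])
    return SurfaceFeatureVector(panel_id=panel_id, values=tuple(values))


def _average_path_length(n: int) -> float:
    """Expected path length of an unsuccessful BST search among n points."""
    if n <= 1:
        return 0.0
    if n == 2:
        return 1.0
    return 2.0 * (math.log(n - 1.0) + np.euler_gamma) - 2.0 * (n - 1.0) / n


@dataclass
class _Tree:
    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    n_node_samples: np.ndarray

    def path_length(self, x: np.ndarray) -> float:
        node, depth = 0, 0
        while self.children_left[node] != -1:
            if x[self.feature[node]] <= self.threshold[node]:
                node = self.children_left[node]
            else:
                node = self.children_right[node]
            depth += 1
        return depth + _average_path_length(int(self.n_node_samples[node]))


class AggregationModel:
    """A fitted isolation forest plus its reference score distribution."""

    def __init__(self, trees: list[_Tree], max_samples: int,
                 reference_scores: np.ndarray, seed: int,
                 feature_names: Sequence[str] = FEATURE_NAMES,
                 schema_version: int = SCHEMA_VERSION):
        self.trees = trees
        self.max_samples = max_samples
        self.reference_scores = np.asarray(reference_scores, dtype=float)
        self.seed = seed
        self.feature_names = tuple(feature_names)
        self.schema_version = schema_version

    # -- scoring -----------------------------------------------------------
    def raw_score(self, values: Sequence[float]) -> float:
        x = np.asarray(values, dtype=float)
        if x.shape != (len(self.feature_names),):
            raise ValueError(f"expected a {len(self.feature_names)}-vector, got {x.shape}")
        mean_path = float(np.mean([t.path_length(x) for t in self.trees]))
        return float(2.0 ** (-mean_path / _average_path_length(self.max_samples)))

    def score(self, v: SurfaceFeatureVector) -> AggregationScore:
        s = self.raw_score(v.values)
        mu = float(self.reference_scores.mean())
        sd = float(self.reference_scores.std(ddof=1))
        z = (s - mu) / sd if sd > 0 else 0.0
        return AggregationScore(score=s, z=z, flagged=z > 2.0)

    # -- persistence -------------------------------------------------------
    def to_json(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "feature_names": list(self.feature_names),
            "max_samples": self.max_samples,
            "seed": self.seed,
            "reference_scores": self.reference_scores.tolist(),
            "trees": [
                {
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "n_node_samples": t.n_node_samples.tolist(),
                }
                for t in self.trees
            ],
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh)

    @classmethod
    def from_json(cls, payload: dict) -> "AggregationModel":
        trees = [
            _Tree(
                children_left=np.asarray(t["children_left"], dtype=int),
                children_right=np.asarray(t["children_right"], dtype=int),
                feature=np.asarray(t["feature"], dtype=int),
                threshold=np.asarray(t["threshold"], dtype=float),
                n_node_samples=np.asarray(t["n_node_samples"], dtype=int),
            )
            for t in payload["trees"]
        ]
        return cls(trees, int(payload["max_samples"]),
                   np.asarray(payload["reference_scores"], dtype=float),
                   int(payload["seed"]), payload["feature_names"],
                   int(payload["schema_version"]))

    @classmethod
    def load(cls, path: str | Path) -> "AggregationModel":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def fit_aggregation_model(panel: Sequence[SurfaceFeatureVector], seed: int,
                          n_estimators: int = 100,
                          reference_panel: Sequence[SurfaceFeatureVector] | None = None,
                          ) -> AggregationModel:
    """Train the isolation forest on a reference panel of feature vectors.

    `reference_panel` optionally supplies a separate panel whose scores form
    the z-score reference distribution; by default the training panel's own
    scores are used.
    """
    if len(panel) < 20:
        raise ValueError(f"training panel too small ({len(panel)} < 20)")
    x = np.array([v.values for v in panel], dtype=float)
    max_samples = min(256, len(panel))
    forest = IsolationForest(n_estimators=n_estimators, max_samples=max_samples,
                             random_state=seed).fit(x)
    trees = []
    for est in forest.estimators_:
        t = est.tree_
        trees.append(_Tree(
            children_left=t.children_left.copy(),
            children_right=t.children_right.copy(),
            feature=t.feature.copy(),
            threshold=t.threshold.copy(),
            n_node_samples=t.n_node_samples.copy(),
        ))
    model = AggregationModel(trees, int(forest.max_samples_),
                             reference_scores=np.zeros(2), seed=seed)
    ref = reference_panel if reference_panel is not None else panel
    model.reference_scores = np.array([model.raw_score(v.values) for v in ref])
    return model


def aggregation_score(model: AggregationModel, v: SurfaceFeatureVector) -> AggregationScore:
    """Anomaly score, z against the reference distribution, flag iff z > 2."""
    return model.score(v)
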