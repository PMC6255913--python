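"""Core in-memory containers for the blood-biomarker pipeline.

The pipeline works on log2-scale, already-normalised expression matrices
(features in rows, samples in columns), per-sample clinical metadata, a
probeset-to-gene annotation map, and named gene-set collections.  All
containers validate their invariants at construction time so that the
downstream statistics never see duplicated identifiers, non-finite values
or misaligned dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("AD", "MCI", "CTL")
GENDERS = ("M", "F")


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id {i!r}")
        seen.add(i)


@dataclass
class ExpressionDataset:
    """A feature x sample expression matrix with aligned identifiers.

    Parameters
    ----------
    matrix : ndarray of shape (n_features, n_samples)
        log2-scale intensities; must be finite.
    feature_ids, sample_ids : list of str
        Unique, ordered identifiers for the rows / columns.
    dataset_label : str
        Batch identity (e.g. the cohort accession) carried through merging.
    """

    matrix: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    dataset_label: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional")
        if self.matrix.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.matrix)):
            g, s = np.argwhere(~np.isfinite(self.matrix))[0]
            raise ValueError(
                f"non-finite expression value at feature {self.feature_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, keep: list[str]) -> "ExpressionDataset":
        """Return a dataset restricted to ``keep`` (given order)."""
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in keep]
        return ExpressionDataset(self.matrix[idx], list(keep), list(self.sample_ids), self.dataset_label)

    def subset_samples(self, keep: list[str]) -> "ExpressionDataset":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return ExpressionDataset(self.matrix[:, idx], list(self.feature_ids), list(keep), self.dataset_label)


@dataclass
class SampleInfo:
    """Clinical metadata for one subject.

    ``group`` is one of AD / MCI / CTL; ``age`` is in years; ``gender`` is
    'M' or 'F' (mapped to a female indicator, F=1, in design matrices).
    Any additional numeric covariates (e.g. RIN) live in
    ``extra_covariates``.
    """

    sample_id: str
    group: str
    age: float
    gender: str
    extra_covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown group {self.group!r} for sample {self.sample_id!r}; "
                f"allowed labels: {', '.join(GROUPS)}"
            )
        if self.gender not in GENDERS:
            raise ValueError(
                f"unknown gender {self.gender!r} for sample {self.sample_id!r}; allowed: M, F"
            )
        self.age = float(self.age)
        if not self.age > 0:
            raise ValueError(f"age must be positive for sample {self.sample_id!r}")

    @property
    def gender_indicator(self) -> float:
        """Female indicator used in design matrices (F=1, M=0)."""
        return 1.0 if self.gender == "F" else 0.0


@dataclass
class FeatureAnnotation:
    """Probeset-to-gene mapping; empty gene_id marks an unannotated feature."""

    feature_id: str
    gene_id: str = ""
    symbol: str = ""


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. canonical pathways) read from a GMT file."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                # deduplicate preserving first occurrence
                seen: set[str] = set()
                self.sets[name] = [m for m in members if not (m in seen or seen.add(m))]

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)
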