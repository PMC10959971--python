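"""Feature-matrix container shared by every pipeline stage.

A :class:`FeatureMatrix` is a plain samples x features array of real values
plus integer class labels and provenance metadata (which backbone or
transform produced the columns).  It round-trips to a CSV file (one row per
sample, label column last) with a JSON sidecar describing provenance, the
on-disk interchange format of the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix"]


@dataclass
class FeatureMatrix:
    """Samples x features real matrix with labels and provenance.

    Parameters
    ----------
    values
        2-D float array, one row per sample.
    labels
        Integer class id per row.
    feature_origin
        Provenance tag: a backbone name, ``"dct"``, ``"fused"`` or
        ``"selected"``.
    class_names
        Optional ordered class names (index ``i`` names label ``i``).
    column_meta
        Optional per-column source descriptors.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_origin: str = "unknown"
    class_names: list[str] | None = None
    column_meta: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"{self.values.shape[0]} rows but {self.labels.shape[0]} labels"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, feature_origin: str | None = None,
                    **meta) -> "FeatureMatrix":
        """Return a copy holding ``values``, labels carried through."""
        return FeatureMatrix(
            values=values,
            labels=self.labels.copy(),
            feature_origin=feature_origin or self.feature_origin,
            class_names=self.class_names,
            meta={**self.meta, **meta},
        )

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        """Write ``<path>`` (CSV, label column last) and ``<path>.json`` sidecar."""
        path = Path(path)
        cols = [f"f{j}" for j in range(self.n_features)]
        df = pd.DataFrame(self.values, columns=cols)
        df["label"] = self.labels
        df.to_csv(path, index=False)
        sidecar = {
            "feature_origin": self.feature_origin,
            "n_samples": int(self.n_samples),
            "n_features": int(self.n_features),
            "class_names": self.class_names,
            "column_meta": self.column_meta,
            **{k: v for k, v in self.meta.items() if _jsonable(v)},
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError(f"{path}: missing 'label' column")
        labels = df.pop("label").to_numpy(dtype=int)
        meta: dict = {}
        origin = "unknown"
        class_names = None
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            origin = meta.pop("feature_origin", "unknown")
            class_names = meta.pop("class_names", None)
            meta.pop("n_samples", None)
            meta.pop("n_features", None)
            meta.pop("column_meta", None)
        return cls(df.to_numpy(dtype=float), labels, feature_origin=origin,
                   class_names=class_names, meta=meta)


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
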