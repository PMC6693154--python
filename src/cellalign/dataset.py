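"""Cells-by-features expression container with condition and cell-type labels.

The container tracks which processing stage (``layer``) the matrix is at:
raw ``counts`` -> ``tp10k`` -> ``log`` -> ``scaled`` -> optionally ``pca``.
Downstream operations declare which layers they accept, which keeps pipelines
honest about normalisation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: sentinel used for cells whose type is unknown; distinct from any real class
UNLABELED = "unlabeled"

LAYERS = ("counts", "tp10k", "log", "scaled", "pca")


@dataclass
class ExpressionDataset:
    """A dense cells x features matrix plus per-cell metadata.

    Parameters
    ----------
    values
        Dense float matrix, one row per cell.
    cell_ids, feature_ids
        Unique row / column names.  When ``layer == "pca"`` the features are
        component names rather than genes.
    condition_of
        Per-cell condition (dataset / stimulus / protocol) name.  Alignment
        requires at least two distinct conditions, but single-condition
        datasets are valid containers (e.g. decoder training slices).
    type_of
        Per-cell cell-type label; :data:`UNLABELED` marks unknown cells.
    layer
        Processing stage of ``values``.
    extras
        Stash for auxiliary matrices carried through the pipeline, e.g. the
        log-layer matrix after scaling (used for variable-gene selection) or
        the gene-space expression matrix after PCA (used as decoder target).
    """

    values: np.ndarray
    cell_ids: list
    feature_ids: list
    condition_of: np.ndarray
    type_of: np.ndarray | None = None
    layer: str = "counts"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = list(self.cell_ids)
        self.feature_ids = list(self.feature_ids)
        self.condition_of = np.asarray(self.condition_of, dtype=object)
        if self.type_of is None:
            self.type_of = np.full(len(self.cell_ids), UNLABELED, dtype=object)
        else:
            self.type_of = np.asarray(self.type_of, dtype=object)
        self._validate()

    def _validate(self):
        n, g = self.values.shape
        if n != len(self.cell_ids):
            raise ValueError(f"{n} rows but {len(self.cell_ids)} cell ids")
        if g != len(self.feature_ids):
            raise ValueError(f"{g} columns but {len(self.feature_ids)} feature ids")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if len(set(self.feature_ids)) != g:
            raise ValueError("duplicate feature ids")
        if self.condition_of.shape != (n,):
            raise ValueError("condition_of length mismatch")
        if self.type_of.shape != (n,):
            raise ValueError("type_of length mismatch")
        if any(c is None or c == "" for c in self.condition_of):
            raise ValueError("every cell needs a condition")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.layer == "counts" and np.any(self.values < 0):
            raise ValueError("counts layer must be non-negative")
        if self.layer == "scaled":
            mean = self.values.mean(axis=0)
            if np.max(np.abs(mean)) > 1e-6:
                raise ValueError("scaled layer: per-feature mean not ~0")
            sd = self.values.std(axis=0)
            nonconst = sd > 1e-12
            if nonconst.any() and np.max(np.abs(sd[nonconst] - 1.0)) > 1e-6:
                raise ValueError("scaled layer: per-feature sd not ~1")

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def conditions(self) -> list:
        """Distinct condition names in sorted (lexicographic) order."""
        return sorted(set(self.condition_of))

    def condition_mask(self, condition) -> np.ndarray:
        return self.condition_of == condition

    # -- derived views --------------------------------------------------
    def with_values(self, values, layer, feature_ids=None, extras=None) -> "ExpressionDataset":
        """New dataset sharing cell metadata but with a different matrix."""
        return ExpressionDataset(
            values=values,
            cell_ids=self.cell_ids,
            feature_ids=self.feature_ids if feature_ids is None else feature_ids,
            condition_of=self.condition_of.copy(),
            type_of=self.type_of.copy(),
            layer=layer,
            extras=dict(self.extras) if extras is None else extras,
        )

    def subset_cells(self, mask) -> "ExpressionDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionDataset(
            values=self.values[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            condition_of=self.condition_of[idx],
            type_of=self.type_of[idx],
            layer=self.layer,
            extras={
                k: (v[idx] if isinstance(v, np.ndarray) and v.ndim >= 1 and v.shape[0] == self.n_cells else v)
                for k, v in self.extras.items()
            },
        )

    def expression_matrix(self) -> np.ndarray:
        """Gene-space matrix: ``values`` unless this is a PCA layer, in which
        case the stashed pre-PCA expression matrix."""
        if self.layer != "pca":
            return self.values
        if "expression" not in self.extras:
            raise ValueError("PCA-layer dataset without stashed expression matrix")
        return self.extras["expression"]

    def expression_feature_ids(self) -> list:
        if self.layer != "pca":
            return list(self.feature_ids)
        return list(self.extras["expression_feature_ids"])
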