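"""Linkage-disequilibrium blocks and lookup.

An :class:`LDBlock` is a symmetric correlation matrix over a contiguous
window of variants; an :class:`LDCollection` indexes several blocks and
answers pairwise r/r² queries, returning 0 for variants in different
blocks (blocks are independent by construction).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PSD_TOL = 1e-8


@dataclass
class LDBlock:
    """Symmetric, unit-diagonal, PSD correlation matrix over ordered variants."""

    variant_ids: list[str]
    R: np.ndarray
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (len(self.variant_ids), len(self.variant_ids)):
            raise ValueError("R shape does not match variant count")

    @property
    def size(self) -> int:
        return len(self.variant_ids)

    def validate(self, tol: float = PSD_TOL) -> None:
        R = self.R
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-9):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(R) > 1 + 1e-12):
            raise ValueError("LD entries outside [-1, 1]")
        w = np.linalg.eigvalsh(R)
        if w.min() < -tol:
            raise ValueError(f"LD matrix not PSD within tolerance (min eig {w.min():.3g})")

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor, computed lazily with a tiny ridge for PSD edge cases."""
        if self._chol is None:
            n = self.size
            try:
                self._chol = np.linalg.cholesky(self.R)
            except np.linalg.LinAlgError:
                self._chol = np.linalg.cholesky(self.R + 1e-10 * np.eye(n))
        return self._chol

    def index_of(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)


class LDCollection:
    """Pairwise LD lookup over disjoint blocks keyed by variant id."""

    def __init__(self, blocks: list[LDBlock]):
        self.blocks = list(blocks)
        self._where: dict[str, tuple[int, int]] = {}
        for bi, block in enumerate(self.blocks):
            for vi, vid in enumerate(block.variant_ids):
                if vid in self._where:
                    raise ValueError(f"variant {vid!r} appears in more than one LD block")
                self._where[vid] = (bi, vi)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._where

    def block_of(self, variant_id: str) -> LDBlock | None:
        loc = self._where.get(variant_id)
        return None if loc is None else self.blocks[loc[0]]

    def r(self, v1: str, v2: str) -> float:
        """Correlation between two variants; 0 across blocks or if unknown."""
        a = self._where.get(v1)
        b = self._where.get(v2)
        if a is None or b is None or a[0] != b[0]:
            return 0.0
        return float(self.blocks[a[0]].R[a[1], b[1]])

    def r2(self, v1: str, v2: str) -> float:
        return self.r(v1, v2) ** 2

    def save(self, directory: str) -> None:
        """Write each block as a dense ``.npy`` matrix plus a variant-id sidecar TSV."""
        os.makedirs(directory, exist_ok=True)
        for i, block in enumerate(self.blocks):
            np.save(os.path.join(directory, f"block{i:04d}.npy"), block.R)
            pd.DataFrame({"variant_id": block.variant_ids}).to_csv(
                os.path.join(directory, f"block{i:04d}.variants.tsv"),
                sep="\t", index=False,
            )

    @classmethod
    def load(cls, directory: str) -> "LDCollection":
        blocks = []
        for fname in sorted(os.listdir(directory)):
            if not fname.endswith(".npy"):
                continue
            stem = fname[: -len(".npy")]
            R = np.load(os.path.join(directory, fname))
            ids = pd.read_csv(
                os.path.join(directory, f"{stem}.variants.tsv"), sep="\t"
            )["variant_id"].astype(str).tolist()
            blocks.append(LDBlock(ids, R))
        return cls(blocks)


def project_to_psd(R: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal of a correlation matrix."""
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    w = np.clip(w, 0.0, None)
    R2 = (V * w) @ V.T
    d = np.sqrt(np.clip(np.diag(R2), tol, None))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return np.clip((R2 + R2.T) / 2.0, -1.0, 1.0)
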