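"""Pluggable linkage-disequilibrium (r-squared) providers.

Clumping needs pairwise r-squared between candidate SNPs.  The contract is a
single method ``r2(snp_a, snp_b) -> float | None`` returning the squared
correlation in [0, 1], or ``None`` when the pair is unknown to the provider.
Two implementations ship: one backed by the synthetic block-AR(1) LD spec and
one backed by a square matrix read from a TSV file.  Reference-panel LD
computation is deliberately out of scope — plug in your own provider.
"""

from __future__ import annotations

from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import pandas as pd

from .simulate import LdBlockSpec


@runtime_checkable
class LdProvider(Protocol):
    def r2(self, snp_a: str, snp_b: str) -> float | None:
        """Pairwise r-squared, or None if the pair is unknown."""
        ...


class SyntheticLdProvider:
    """r-squared from an :class:`LdBlockSpec` over named SNPs.

    Within a block r2(i, j) = rho^(2|i-j|); across blocks 0.  SNPs outside the
    spec are unknown (None).
    """

    def __init__(self, spec: LdBlockSpec, snp_ids: Sequence[str] | None = None):
        if snp_ids is None:
            snp_ids = [f"rs{i + 1}" for i in range(spec.m_snps)]
        if len(snp_ids) != spec.m_snps:
            raise ValueError("snp_ids length must match the LD spec")
        self.spec = spec
        blocks = spec.block_index()
        offs = spec.offsets()
        self._where = {s: (int(blocks[i]), int(offs[i])) for i, s in enumerate(snp_ids)}

    def r2(self, snp_a: str, snp_b: str) -> float | None:
        a = self._where.get(snp_a)
        b = self._where.get(snp_b)
        if a is None or b is None:
            return None
        if snp_a == snp_b:
            return 1.0
        if a[0] != b[0]:
            return 0.0
        return float((self.spec.rho ** 2) ** abs(a[1] - b[1]))


class MatrixLdProvider:
    """r-squared looked up in a symmetric square matrix keyed by SNP id."""

    def __init__(self, matrix: pd.DataFrame):
        if list(matrix.index) != list(matrix.columns):
            raise ValueError("LD matrix must be square with identical row/column SNP ids")
        self._m = matrix
        self._ids = set(matrix.index)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MatrixLdProvider":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def r2(self, snp_a: str, snp_b: str) -> float | None:
        if snp_a not in self._ids or snp_b not in self._ids:
            return None
        return float(self._m.at[snp_a, snp_b])


class IndependentLdProvider:
    """All pairs uncorrelated (r2 = 0); useful for pre-pruned instrument sets."""

    def r2(self, snp_a: str, snp_b: str) -> float | None:
        return 1.0 if snp_a == snp_b else 0.0
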