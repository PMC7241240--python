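"""Core data containers: single omic blocks and grouped multi-block studies.

An :class:`OmicBlock` is one omic dataset (metabolomics, proteomics, ...)
stored as a samples x features matrix.  A :class:`GroupedStudy` bundles
several blocks measured on the *same* ordered samples together with a binary
case/control assignment; the first block is the "centric" block whose
features are eventually ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OmicBlock", "GroupedStudy"]


@dataclass
class OmicBlock:
    """One omic dataset: an ``n x h`` numeric matrix with identifiers.

    Parameters
    ----------
    name
        Short omic-type tag, e.g. ``"metabolomics"``.
    sample_ids, feature_ids
        Ordered, unique identifiers for rows and columns of ``values``.
    values
        Numeric matrix with samples in rows and features in columns.
    """

    name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, h = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"block {self.name!r}: {n} rows but {len(self.sample_ids)} sample ids"
            )
        if h != len(self.feature_ids):
            raise ValueError(
                f"block {self.name!r}: {h} columns but {len(self.feature_ids)} feature ids"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"block {self.name!r}: duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError(f"block {self.name!r}: duplicate feature ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"block {self.name!r}: non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, feature {self.feature_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    def subset_features(self, feature_ids: list[str]) -> "OmicBlock":
        """Restrict to the given features, preserving current order."""
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        idx = [self.feature_ids.index(f) for f in keep]
        return OmicBlock(self.name, self.sample_ids, keep, self.values[:, idx])

    def subset_samples(self, sample_ids: list[str]) -> "OmicBlock":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OmicBlock(self.name, list(sample_ids), self.feature_ids, self.values[idx])


@dataclass
class GroupedStudy:
    """Ordered blocks on a shared sample axis plus a binary group assignment.

    ``blocks[0]`` is the centric block (the omic whose features are ranked).
    Group labels are the integers 1 and 2; differential quantities are always
    group 1 minus group 2.
    """

    blocks: list[OmicBlock]
    group_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("a study needs at least one block")
        ref = self.blocks[0].sample_ids
        for b in self.blocks[1:]:
            if b.sample_ids != ref:
                raise ValueError(
                    f"block {b.name!r} sample ids differ from centric block"
                )
        missing = [s for s in ref if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group label: {missing[:5]}")
        bad = sorted({g for g in self.group_of.values()} - {1, 2})
        if bad:
            raise ValueError(f"group labels must be 1 or 2, got {bad}")
        for g in (1, 2):
            if sum(self.group_of[s] == g for s in ref) < 3:
                raise ValueError(
                    f"group {g} has fewer than 3 samples; correlation "
                    "estimation refused"
                )

    @property
    def centric(self) -> OmicBlock:
        return self.blocks[0]

    @property
    def sample_ids(self) -> list[str]:
        return self.blocks[0].sample_ids

    def labels(self) -> np.ndarray:
        """Group label (1 or 2) per sample, in sample order."""
        return np.array([self.group_of[s] for s in self.sample_ids], dtype=int)

    def group_matrix(self, block: int | str, group: int) -> np.ndarray:
        """Rows of one block belonging to one group (copy)."""
        b = self.get_block(block)
        mask = self.labels() == group
        return b.values[mask].copy()

    def get_block(self, block: int | str) -> OmicBlock:
        if isinstance(block, int):
            return self.blocks[block]
        for b in self.blocks:
            if b.name == block:
                return b
        raise KeyError(f"no block named {block!r}")

    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]
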