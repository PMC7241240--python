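"""Reading and writing omic blocks, group labels, p-values and networks.

All tabular inputs are delimited text (TSV by default, CSV when the file
extension is ``.csv``) with one header row and one identifier column.
Networks are written as GraphML plus a flat TSV edge list so that any graph
viewer can reproduce the node p-value / score styling.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .blocks import OmicBlock
from .network import DifferentialNetwork

__all__ = [
    "read_omic_block",
    "read_groups",
    "read_pvalues",
    "filter_by_pvalue",
    "write_network",
    "read_network",
    "write_edge_list",
    "write_ranking",
]

log = logging.getLogger("mota")


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_omic_block(
    path: str | Path,
    name: str,
    orientation: str = "samples-in-rows",
    impute: bool = False,
) -> OmicBlock:
    """Load one omic matrix from delimited text.

    Parameters
    ----------
    path
        TSV/CSV file with a header row and the row identifiers in the first
        column.
    name
        Omic-type tag attached to the block.
    orientation
        ``"samples-in-rows"`` (default) or ``"features-in-rows"``; the latter
        transposes the matrix after reading.
    impute
        If true, missing cells are replaced by the per-feature mean;
        by default any missing cell is an error (correlation estimation on
        silently imputed data is easy to get wrong, so rejection is the
        default).

    Constant-valued (zero-variance) features are dropped with a warning: they
    cannot be standardized and carry no correlation signal.
    """
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate column id {dup!r}")

    # locate non-numeric cells before any coercion so the error names them
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row "
            f"{df.index[r]!r}, column {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        if not impute:
            raise ValueError(
                f"{path}: missing value at row {df.index[r]!r}, column "
                f"{df.columns[c]!r} (pass impute=True for per-feature mean "
                "imputation)"
            )
        log.warning("%s: imputing %d missing cells with feature means",
                    path, int(numeric.isna().to_numpy().sum()))

    if orientation == "features-in-rows":
        numeric = numeric.T
    if impute:
        numeric = numeric.fillna(numeric.mean(axis=0))

    variances = numeric.var(axis=0, ddof=1).to_numpy()
    constant = np.asarray(variances == 0) | np.isnan(variances)
    if constant.any():
        dropped = list(numeric.columns[constant])
        warnings.warn(
            f"{path}: dropping {len(dropped)} zero-variance feature(s): "
            f"{dropped[:5]}",
            stacklevel=2,
        )
        log.warning("%s: dropped zero-variance features: %s", path, dropped)
        numeric = numeric.loc[:, ~constant]

    return OmicBlock(
        name=name,
        sample_ids=list(numeric.index),
        feature_ids=list(numeric.columns),
        values=numeric.to_numpy(dtype=float),
    )


def read_groups(path: str | Path) -> dict[str, int]:
    """Read a two-column (sample_id, label) file into a sample -> {1,2} map.

    Exactly two distinct labels are required; they are mapped to 1 and 2 in
    order of first appearance (so the first label seen becomes group 1, and
    all differential quantities are that group minus the other).  The mapping
    is logged because it fixes the sign convention of every delta.
    """
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, found {df.shape[1]}")
    seen: dict[str, int] = {}
    mapping: dict[str, int] = {}
    for sample, label in df.itertuples(index=False):
        if label not in seen:
            seen[label] = len(seen) + 1
        if sample in mapping:
            raise ValueError(f"{path}: duplicate sample id {sample!r}")
        mapping[sample] = seen[label]
    if len(seen) != 2:
        raise ValueError(
            f"{path}: need exactly 2 distinct labels, found {len(seen)}: "
            f"{sorted(seen)}"
        )
    log.info("group mapping from %s: %s", path,
             {lab: g for lab, g in seen.items()})
    return mapping


def read_pvalues(path: str | Path) -> dict[str, float]:
    """Read a two-column (feature_id, p_value) file."""
    df = pd.read_csv(path, sep=_sep_for(path), header=None, comment="#")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, found {df.shape[1]}")
    out = {str(f): float(p) for f, p in df.itertuples(index=False)}
    bad = {f: p for f, p in out.items() if not (0 <= p <= 1)}
    if bad:
        raise ValueError(f"{path}: p-values outside [0,1]: {bad}")
    return out


def filter_by_pvalue(block: OmicBlock, pvals: dict[str, float], alpha: float) -> OmicBlock:
    """Keep features with p strictly below ``alpha`` (significance pre-filter).

    Every feature in the block must have a p-value; a missing one is an error
    rather than an implicit keep/drop.
    """
    missing = [f for f in block.feature_ids if f not in pvals]
    if missing:
        raise ValueError(
            f"block {block.name!r}: no p-value for feature(s) {missing[:5]}"
        )
    keep = [f for f in block.feature_ids if pvals[f] < alpha]
    if not keep:
        warnings.warn(
            f"block {block.name!r}: no feature passes p < {alpha}; "
            "empty block returned",
            stacklevel=2,
        )
    idx = [block.feature_ids.index(f) for f in keep]
    return OmicBlock(block.name, block.sample_ids, keep,
                     block.values[:, idx].reshape(block.n_samples, len(keep)))


# ---------------------------------------------------------------------------
# networks and tables

def write_network(net: DifferentialNetwork, path: str | Path) -> None:
    """Write a network as GraphML (node/edge attributes preserved)."""
    nx.write_graphml(net.to_string_graph(), str(path))


def read_network(path: str | Path) -> DifferentialNetwork:
    return DifferentialNetwork.from_string_graph(nx.read_graphml(str(path)))


def write_edge_list(net: DifferentialNetwork, path: str | Path) -> None:
    """Flat TSV edge list: source/target omic+feature, kind, correlations."""
    rows = []
    for (uo, uf), (vo, vf), attrs in sorted(net.graph.edges(data=True)):
        rows.append({
            "source_omic": uo, "source_feature": uf,
            "target_omic": vo, "target_feature": vf,
            "kind": attrs["kind"],
            "corr_group1": attrs["corr_group1"],
            "corr_group2": attrs["corr_group2"],
            "delta": attrs["delta"],
        })
    pd.DataFrame(
        rows,
        columns=["source_omic", "source_feature", "target_omic",
                 "target_feature", "kind", "corr_group1", "corr_group2",
                 "delta"],
    ).to_csv(path, sep="\t", index=False)


def write_ranking(table: pd.DataFrame, path: str | Path) -> None:
    """Write the ranking table as TSV with stable float formatting."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
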