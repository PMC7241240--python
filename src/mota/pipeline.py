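"""End-to-end orchestration: differential network construction and ranking.

The pipeline follows the method's framework: build the intra-omic
differential network on the centric block (graphical lasso + permutation
test), add inter-omic edges per ancillary block (per-group rgCCA,
differential canonical similarity), convert per-feature p-values to
z-scores, and rank centric features by the activity score
``M_k = z_k + sum_l z_lk``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .blocks import GroupedStudy
from .intra import build_intra_network
from .network import DifferentialNetwork
from .rgcca import build_inter_edges
from .scoring import feature_pvalues, mota_scores, p_to_z, rank_features

__all__ = ["RunParams", "RunConfig", "run_study", "run", "load_config"]

log = logging.getLogger("mota")


@dataclass
class RunParams:
    """All numeric knobs of the pipeline with their defaults.

    Defaults follow the method's stated settings: 1000 permutations, 2.5%
    tails for intra edges, rgCCA with the horst scheme and tau = 0, a 0.5
    cutoff on |delta_cc|, and the sqrt(m) Stouffer denominator.
    """

    seed: int = 0
    permutation_n: int = 1000
    permutation_tail: float = 0.025
    permutation_pooled: bool = True
    glasso_folds: int = 5
    glasso_grid_size: int = 20
    glasso_grid_min: float = 0.01
    rgcca_tau: float = 0.0
    rgcca_scheme: str = "horst"
    rgcca_tol: float = 1e-8
    rgcca_max_iter: int = 1000
    inter_threshold: float = 0.5
    score_denominator: str = "sqrt_m"


@dataclass
class RunConfig:
    """File-level run description (paths + parameters)."""

    block_paths: list[dict]  # {name, path, orientation?, pvalues?, filter_alpha?}
    groups_path: str
    centric: str
    outdir: str
    params: RunParams = field(default_factory=RunParams)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config.

    Expected layout::

        blocks:
          - {name: metabolomics, path: metab.tsv}
          - {name: proteomics, path: prot.tsv, pvalues: prot_p.tsv,
             filter_alpha: 0.05}
        groups: groups.tsv
        centric: metabolomics
        outdir: results/
        seed: 1
        permutation: {n: 1000, tail: 0.025, pooled: true}
        glasso: {folds: 5, grid_size: 20, grid_min: 0.01}
        rgcca: {tau: 0.0, scheme: horst, tol: 1e-8, max_iter: 1000}
        inter: {threshold: 0.5}
        score: {denominator: sqrt_m}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    p = RunParams(seed=int(raw.get("seed", 0)))
    for section, prefix in (("permutation", "permutation"), ("glasso", "glasso"),
                            ("rgcca", "rgcca"), ("inter", "inter"),
                            ("score", "score")):
        for key, val in (raw.get(section) or {}).items():
            attr = f"{prefix}_{key}"
            if not hasattr(p, attr):
                raise ValueError(f"unknown config key {section}.{key}")
            setattr(p, attr, type(getattr(p, attr))(val))
    return RunConfig(
        block_paths=list(raw["blocks"]),
        groups_path=str(raw["groups"]),
        centric=str(raw["centric"]),
        outdir=str(raw["outdir"]),
        params=p,
    )


def run_study(
    study: GroupedStudy,
    params: RunParams | None = None,
    external_pvalues: dict[str, dict[str, float]] | None = None,
) -> tuple[DifferentialNetwork, pd.DataFrame, dict]:
    """Run the full method on an in-memory study.

    ``external_pvalues`` optionally maps a block name to precomputed
    per-feature p-values (e.g. count-model p-values for sequencing data),
    bypassing the built-in t-test for that block.

    Returns ``(network, ranking table, metadata)``.
    """
    params = params or RunParams()
    centric = study.centric
    meta: dict = {
        "version": __version__,
        "seed": params.seed,
        "params": dataclasses.asdict(params),
        "blocks": {b.name: b.n_features for b in study.blocks},
        "n_samples": {g: int((study.labels() == g).sum()) for g in (1, 2)},
    }

    # --- intra-omic stage -------------------------------------------------
    intra = build_intra_network(
        study,
        n_perm=params.permutation_n,
        seed=params.seed,
        tail=params.permutation_tail,
        folds=params.glasso_folds,
        grid_size=params.glasso_grid_size,
        grid_min=params.glasso_grid_min,
        pooled=params.permutation_pooled,
    )
    meta["rho"] = {"group1": intra.rho[0], "group2": intra.rho[1]}
    meta["null_quantiles"] = {"lower": intra.lower_cut, "upper": intra.upper_cut,
                              "tail": params.permutation_tail,
                              "convention": "inclusive linear (type 7)"}
    meta["n_intra_edges"] = len(intra.edges)

    net = DifferentialNetwork()
    feats = centric.feature_ids
    for f in feats:
        net.add_node(centric.name, f)
    for i, j in sorted(intra.edges):
        net.add_edge(
            (centric.name, feats[i]), (centric.name, feats[j]),
            kind="intra",
            corr_group1=intra.pc1[i, j],
            corr_group2=intra.pc2[i, j],
        )

    # --- inter-omic stage, one ancillary block at a time ------------------
    meta["n_inter_edges"] = {}
    for b in study.blocks[1:]:
        inter = build_inter_edges(
            study, b.name,
            threshold=params.inter_threshold,
            tau=params.rgcca_tau,
            tol=params.rgcca_tol,
            max_iter=params.rgcca_max_iter,
        )
        for i, j in sorted(inter.edges):
            net.add_edge(
                (centric.name, feats[i]), (b.name, b.feature_ids[j]),
                kind="inter",
                corr_group1=inter.cc1[i, j],
                corr_group2=inter.cc2[i, j],
            )
        meta["n_inter_edges"][b.name] = len(inter.edges)

    # --- scoring ----------------------------------------------------------
    external_pvalues = external_pvalues or {}
    p_of: dict[tuple[str, str], float] = {}
    for b in study.blocks:
        if b.name in external_pvalues:
            pvals = external_pvalues[b.name]
            missing = [f for f in b.feature_ids if f not in pvals]
            if missing:
                raise ValueError(
                    f"external p-values for block {b.name!r} missing "
                    f"features {missing[:5]}"
                )
            for f in b.feature_ids:
                p_of[(b.name, f)] = float(pvals[f])
        else:
            for f, p in feature_pvalues(b, study).items():
                p_of[(b.name, f)] = p
    z_of = {node: p_to_z(p) for node, p in p_of.items()}

    labels = study.labels()
    mean_diff = (centric.values[labels == 1].mean(axis=0)
                 - centric.values[labels == 2].mean(axis=0))
    directions = {f: int(np.sign(d)) for f, d in zip(feats, mean_diff)}

    scores = mota_scores(
        net, z_of, p_of, centric=centric.name, directions=directions,
        denominator=params.score_denominator,
    )
    ranking = rank_features(scores, centric=centric.name)

    for f, s in scores.items():
        net.set_node_attrs(centric.name, f, p_value=s.p, z=s.z, mota_score=s.mota)
    for (omic, f), p in p_of.items():
        if omic != centric.name and (omic, f) in net.graph:
            net.set_node_attrs(omic, f, p_value=p, z=z_of[(omic, f)])

    return net, ranking, meta


def run(config: RunConfig) -> tuple[DifferentialNetwork, pd.DataFrame, dict]:
    """Load inputs per config, run the pipeline, and write all outputs.

    Outputs in ``config.outdir``: ``network.graphml``, ``edges.tsv``,
    ``ranking.tsv`` and ``run_metadata.json``.  Any stage failure aborts
    with the stage name and removes partial outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = [outdir / n for n in
               ("network.graphml", "edges.tsv", "ranking.tsv", "run_metadata.json")]
    stage = "load"
    try:
        groups = mio.read_groups(config.groups_path)
        blocks = []
        external: dict[str, dict[str, float]] = {}
        centric_entry = [e for e in config.block_paths if e["name"] == config.centric]
        if not centric_entry:
            raise ValueError(
                f"centric block {config.centric!r} not among configured blocks"
            )
        ordered = centric_entry + [e for e in config.block_paths
                                   if e["name"] != config.centric]
        for entry in ordered:
            block = mio.read_omic_block(
                entry["path"], entry["name"],
                orientation=entry.get("orientation", "samples-in-rows"),
            )
            if "pvalues" in entry:
                pvals = mio.read_pvalues(entry["pvalues"])
                if "filter_alpha" in entry:
                    block = mio.filter_by_pvalue(
                        block, pvals, float(entry["filter_alpha"])
                    )
                external[entry["name"]] = pvals
            blocks.append(block)
        study = GroupedStudy(blocks=blocks, group_of={
            s: groups[s] for s in blocks[0].sample_ids if s in groups
        } if all(s in groups for s in blocks[0].sample_ids) else _missing(groups, blocks))

        stage = "pipeline"
        net, ranking, meta = run_study(study, config.params, external)

        stage = "write"
        mio.write_network(net, outputs[0])
        mio.write_edge_list(net, outputs[1])
        mio.write_ranking(ranking, outputs[2])
        meta["config"] = {
            "blocks": config.block_paths,
            "groups": config.groups_path,
            "centric": config.centric,
            "outdir": config.outdir,
        }
        with open(outputs[3], "w") as fh:
            json.dump(meta, fh, indent=1, default=float)
        return net, ranking, meta
    except Exception as exc:
        for f in outputs:
            f.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc


def _missing(groups: dict[str, int], blocks) -> dict[str, int]:
    missing = [s for s in blocks[0].sample_ids if s not in groups]
    raise ValueError(f"samples in data but absent from label file: {missing[:5]}")
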