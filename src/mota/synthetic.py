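"""Grouped multi-omic fixture generator with machine-readable ground truth.

The generator emulates the statistical structure the pipeline assumes:

* the centric block is multivariate normal per group, with group-specific
  partial correlations planted directly in the precision matrix
  (unit diagonal, theta_ij = -pc_ij, diagonally loaded to positive definite
  if needed);
* ancillary-block features are tied to centric features through shared
  latent factors — an ancillary feature linked with strength s is
  ``s * factor + sqrt(1 - s^2) * noise``, giving an analytically known
  cross-correlation of s per group;
* selected centric features receive a between-group mean shift in SD units.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawn keys, one stream per (block, group), so adding a block never perturbs
the draws of earlier blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .blocks import GroupedStudy, OmicBlock

__all__ = ["FixtureSpec", "GroundTruth", "generate", "null_study",
           "random_sparse_precision", "write_study"]


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic grouped multi-omic study.

    ``intra_edges`` plants group-specific partial correlations
    ``(i, j, pc_group1, pc_group2)`` between centric features.
    ``cross_links`` ties an ancillary feature to a centric feature through a
    shared latent factor: ``(centric_idx, block_name, other_idx, s1, s2)``
    with per-group strengths (= population cross-correlations).
    ``mean_shifts`` maps centric feature index -> effect size in SD units
    added to group 1.
    """

    n_per_group: int = 50
    blocks: list[tuple[str, int]] = field(
        default_factory=lambda: [("metabolomics", 15)]
    )
    intra_edges: list[tuple[int, int, float, float]] = field(default_factory=list)
    cross_links: list[tuple[int, str, int, float, float]] = field(default_factory=list)
    mean_shifts: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if not self.blocks:
            raise ValueError("at least one (centric) block is required")
        names = [b[0] for b in self.blocks]
        if len(set(names)) != len(names):
            raise ValueError("block names must be unique")
        h0 = self.blocks[0][1]
        for i, j, *_ in self.intra_edges:
            if not (0 <= i < h0 and 0 <= j < h0 and i != j):
                raise ValueError(f"intra edge ({i},{j}) out of range for h={h0}")
        sizes = dict(self.blocks)
        seen = set()
        for ci, bname, oi, s1, s2 in self.cross_links:
            if bname not in sizes or bname == self.blocks[0][0]:
                raise ValueError(f"cross link references unknown ancillary block {bname!r}")
            if not (0 <= ci < h0 and 0 <= oi < sizes[bname]):
                raise ValueError(f"cross link ({ci},{bname},{oi}) out of range")
            if not (abs(s1) < 1 and abs(s2) < 1):
                raise ValueError("link strengths must lie in (-1, 1)")
            if (bname, oi) in seen:
                raise ValueError(
                    f"ancillary feature {bname}[{oi}] linked more than once"
                )
            seen.add((bname, oi))
        for i in self.mean_shifts:
            if not 0 <= i < h0:
                raise ValueError(f"mean shift index {i} out of range")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks downstream."""

    intra_pairs: list[tuple[int, int, float, float]]
    cross_pairs: list[tuple[int, str, int, float, float]]
    shifted_features: dict[int, float]
    precision_group1: np.ndarray | None = None
    precision_group2: np.ndarray | None = None

    def differential_intra(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j, a, b in self.intra_pairs if a != b]

    def differential_cross(self) -> list[tuple[int, str, int]]:
        return [(i, b, j) for i, b, j, a, c in self.cross_pairs if a != c]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _planted_precision(h: int, edges: list[tuple[int, int, float]]) -> np.ndarray:
    """Unit-diagonal precision with theta_ij = -pc_ij, loaded to PD.

    The minimal diagonal load (powers of 2 of machine epsilon scale) that
    makes the Cholesky factorization succeed is applied, so the planted
    partial correlations stay interpretable to high accuracy.
    """
    theta = np.eye(h)
    for i, j, pc in edges:
        theta[i, j] = theta[j, i] = -pc
    eps = 0.0
    for _ in range(60):
        try:
            np.linalg.cholesky(theta + eps * np.eye(h))
            break
        except np.linalg.LinAlgError:
            eps = max(2 * eps, 1e-10)
    else:
        raise ValueError(
            "planted precision cannot be made positive definite; "
            "reduce the planted partial correlations"
        )
    return theta + eps * np.eye(h)


def random_sparse_precision(
    h: int,
    seed: int | np.random.Generator,
    density: float = 0.15,
    strength: tuple[float, float] = (0.2, 0.4),
) -> np.ndarray:
    """Random sparse positive-definite precision matrix.

    Off-diagonal support is Bernoulli(density) on the upper triangle with
    partial correlations of random sign and magnitude in ``strength``;
    the matrix is diagonally loaded to positive definiteness.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = []
    for i in range(h):
        for j in range(i + 1, h):
            if rng.random() < density:
                mag = rng.uniform(*strength)
                edges.append((i, j, float(rng.choice([-1, 1]) * mag)))
    theta = _planted_precision(h, edges)
    # ensure comfortable conditioning, not just numerical PD
    eig = np.linalg.eigvalsh(theta)
    if eig[0] < 0.05:
        theta += (0.05 - eig[0]) * np.eye(h)
    return theta


def generate(spec: FixtureSpec) -> tuple[GroupedStudy, GroundTruth]:
    """Draw a grouped study from the fixture spec.

    Returns the study plus the ground truth actually planted (including the
    exact per-group centric precision matrices after any diagonal loading).
    """
    spec.validate()
    h0 = spec.blocks[0][1]
    thetas = {}
    covs = {}
    for g in (1, 2):
        col = 2 if g == 1 else 3  # pc_group1 / pc_group2 columns
        edges = [(i, j, e[col]) for e in spec.intra_edges for i, j in [(e[0], e[1])]]
        theta = _planted_precision(h0, edges)
        thetas[g] = theta
        covs[g] = np.linalg.inv(theta)

    n = spec.n_per_group
    sample_ids = [f"S{g}_{i:03d}" for g in (1, 2) for i in range(n)]
    group_of = {s: (1 if s.startswith("S1_") else 2) for s in sample_ids}

    centric_name = spec.blocks[0][0]
    centric_rows = []
    factors = {}  # (group,) -> n x h0 standardized centric draws
    for g in (1, 2):
        rng = _rng(spec.seed, 0, g)
        chol = np.linalg.cholesky(covs[g])
        X = rng.standard_normal((n, h0)) @ chol.T
        # standardized latent factors before mean shifts: these drive the
        # ancillary links so the planted cross-correlation is exact
        factors[g] = X / np.sqrt(np.diag(covs[g]))
        if g == 1:
            for idx, shift in spec.mean_shifts.items():
                X[:, idx] += shift * np.sqrt(covs[g][idx, idx])
        centric_rows.append(X)
    blocks = [OmicBlock(
        centric_name,
        sample_ids,
        [f"{centric_name}_f{i}" for i in range(h0)],
        np.vstack(centric_rows),
    )]

    links_by_block: dict[str, list[tuple[int, int, float, float]]] = {}
    for ci, bname, oi, s1, s2 in spec.cross_links:
        links_by_block.setdefault(bname, []).append((ci, oi, s1, s2))

    for b_idx, (bname, hb) in enumerate(spec.blocks[1:], start=1):
        rows = []
        for g in (1, 2):
            rng = _rng(spec.seed, b_idx, g)
            noise = rng.standard_normal((n, hb))
            X = spec.noise_sd * noise
            for ci, oi, s1, s2 in links_by_block.get(bname, []):
                s = s1 if g == 1 else s2
                X[:, oi] = spec.noise_sd * (
                    s * factors[g][:, ci] + np.sqrt(1 - s**2) * noise[:, oi]
                )
            rows.append(X)
        blocks.append(OmicBlock(
            bname,
            sample_ids,
            [f"{bname}_f{i}" for i in range(hb)],
            np.vstack(rows),
        ))

    truth = GroundTruth(
        intra_pairs=list(spec.intra_edges),
        cross_pairs=list(spec.cross_links),
        shifted_features=dict(spec.mean_shifts),
        precision_group1=thetas[1],
        precision_group2=thetas[2],
    )
    return GroupedStudy(blocks=blocks, group_of=group_of), truth


def null_study(
    n_per_group: int,
    blocks: list[tuple[str, int]],
    seed: int,
    sparse_centric: bool = True,
) -> GroupedStudy:
    """Both groups drawn from one distribution: no differential structure.

    The centric block uses a random sparse positive-definite precision
    (shared by the two groups) so that the null still has realistic
    conditional-dependence structure; ancillary blocks are independent
    noise.
    """
    h0 = blocks[0][1]
    theta = (random_sparse_precision(h0, _rng(seed, 99))
             if sparse_centric else np.eye(h0))
    cov = np.linalg.inv(theta)
    chol = np.linalg.cholesky(cov)
    n = n_per_group
    sample_ids = [f"S{g}_{i:03d}" for g in (1, 2) for i in range(n)]
    group_of = {s: (1 if s.startswith("S1_") else 2) for s in sample_ids}
    out = []
    for b_idx, (bname, hb) in enumerate(blocks):
        rows = []
        for g in (1, 2):
            rng = _rng(seed, b_idx, g)
            X = rng.standard_normal((n, hb))
            if b_idx == 0:
                X = X @ chol.T
            rows.append(X)
        out.append(OmicBlock(
            bname, sample_ids,
            [f"{bname}_f{i}" for i in range(hb)],
            np.vstack(rows),
        ))
    return GroupedStudy(blocks=out, group_of=group_of)


def write_study(study: GroupedStudy, truth: GroundTruth | None, outdir: str | Path) -> None:
    """Write block TSVs, the group file and (optionally) ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for b in study.blocks:
        b.to_frame().to_csv(outdir / f"{b.name}.tsv", sep="\t")
    with open(outdir / "groups.tsv", "w") as fh:
        for s in study.sample_ids:
            fh.write(f"{s}\tgroup{study.group_of[s]}\n")
    if truth is not None:
        payload = asdict(truth)
        for key in ("precision_group1", "precision_group2"):
            if payload[key] is not None:
                payload[key] = np.asarray(payload[key]).tolist()
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(payload, fh, indent=1)
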