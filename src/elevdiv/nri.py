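"""Phylogenetic community structure: MPD and the net relatedness index.

The net relatedness index standardises a community's mean pairwise
patristic distance (MPD) against a randomisation null:

    NRI = -1 x (MPD_obs - mean(MPD_null)) / sd(MPD_null)

so NRI > 0 means co-occurring species are more closely related than chance
(phylogenetic clustering, e.g. habitat filtering) and NRI < 0 means
overdispersion (e.g. competitive exclusion). The null distribution is built
from randomly generated communities of the same size drawn from a species
pool — by default every species recorded on the mountain.

Two null schemes are provided: ``pool_draw`` (uniform sampling of taxa
without replacement from the pool) and ``taxa_label_shuffle`` (permuting
tip labels of the pool subtree and reading off the community's positions).
For presence-only MPD the two induce the same null distribution; both are
kept because different community-phylogenetics packages default to
different descriptions of the randomisation. The scheme, replicate count
and seed are echoed in every result. The null standard deviation uses the
sample (n-1) form.
"""

from __future__ import annotations

import logging
import math
import secrets
from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .belts import BeltMatrix
from .phylodiv import patristic_distance_matrix, tip_labels

logger = logging.getLogger(__name__)

__all__ = ["NullModelConfig", "NriResult", "mpd", "nri", "nri_profile"]

_SCHEMES = ("pool_draw", "taxa_label_shuffle")


@dataclass(frozen=True)
class NullModelConfig:
    """Configuration of the NRI randomisation null.

    ``pool=None`` means the pool is every tip of the tree handed to
    :func:`nri` / :func:`nri_profile` (i.e. all species recorded on the
    mountain). ``seed=None`` draws a seed from system entropy and logs it,
    so library use stays reproducible after the fact; pipeline runs always
    pass an explicit seed.
    """

    n_reps: int = 1000
    scheme: str = "pool_draw"
    seed: int | None = None
    pool: frozenset[str] | None = None

    def __post_init__(self):
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}")


@dataclass(frozen=True)
class NriResult:
    mpd_obs: float
    null_mean: float
    null_sd: float
    nri: float  # NaN when the null distribution is degenerate
    rank_p: float
    n_taxa: int
    n_reps: int
    seed: int
    scheme: str
    degenerate: bool = False


def mpd(tree: dendropy.Tree, taxon_set: Sequence[str]) -> float:
    """Mean patristic distance over all unordered pairs of the taxon set."""
    taxa = sorted(set(taxon_set))
    if len(taxa) < 2:
        raise ValueError("MPD requires at least 2 taxa")
    dm = patristic_distance_matrix(tree, taxa)
    iu = np.triu_indices(len(taxa), k=1)
    return float(dm[iu].mean())


def _mpd_from_dm(dm: np.ndarray, idx: np.ndarray) -> float:
    k = len(idx)
    sub = dm[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


def _null_mpds(
    dm: np.ndarray, comm_idx: np.ndarray, scheme: str, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    n = dm.shape[0]
    k = len(comm_idx)
    out = np.empty(n_reps)
    if scheme == "pool_draw":
        for r in range(n_reps):
            out[r] = _mpd_from_dm(dm, rng.choice(n, size=k, replace=False))
    else:  # taxa_label_shuffle: permute tip labels, read off community positions
        for r in range(n_reps):
            out[r] = _mpd_from_dm(dm, rng.permutation(n)[comm_idx])
    return out


def _resolve_seed(config: NullModelConfig) -> int:
    if config.seed is not None:
        return int(config.seed)
    seed = secrets.randbelow(2**31)
    logger.info("no null-model seed supplied; drew seed %d from entropy", seed)
    return seed


def _nri_from_dm(
    dm: np.ndarray, comm_idx: np.ndarray, config: NullModelConfig, seed: int
) -> NriResult:
    k = len(comm_idx)
    mpd_obs = _mpd_from_dm(dm, comm_idx)
    rng = np.random.default_rng(seed)
    nulls = _null_mpds(dm, comm_idx, config.scheme, config.n_reps, rng)
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1))
    rank_p = float((1 + np.sum(nulls <= mpd_obs)) / (config.n_reps + 1))
    # degeneracy test is relative: identical null communities can differ by
    # float summation order, leaving an sd of ~1e-16 instead of exactly 0
    if null_sd <= 1e-12 * max(1.0, abs(null_mean)):
        logger.warning(
            "degenerate null distribution (sd=0) for community of %d taxa; NRI undefined", k
        )
        return NriResult(
            mpd_obs, null_mean, null_sd, math.nan, rank_p, k,
            config.n_reps, seed, config.scheme, degenerate=True,
        )
    value = -(mpd_obs - null_mean) / null_sd
    return NriResult(
        mpd_obs, null_mean, null_sd, value, rank_p, k, config.n_reps, seed, config.scheme
    )


def nri(
    tree: dendropy.Tree, community: Sequence[str], config: NullModelConfig | None = None
) -> NriResult:
    """Net relatedness index of one community against the randomisation null.

    The community must have >= 2 taxa, all contained in the pool. A
    degenerate null (sd = 0, e.g. community == pool under label shuffling)
    yields ``nri = NaN`` with ``degenerate=True`` rather than a silent zero.
    """
    config = config or NullModelConfig()
    comm = sorted(set(community))
    if len(comm) < 2:
        raise ValueError("NRI requires a community of >= 2 taxa")
    pool = sorted(config.pool) if config.pool is not None else sorted(tip_labels(tree))
    missing = set(comm) - set(pool)
    if missing:
        raise ValueError(f"community taxa outside the pool: {sorted(missing)}")
    dm = patristic_distance_matrix(tree, pool)
    pos = {t: i for i, t in enumerate(pool)}
    comm_idx = np.array([pos[t] for t in comm])
    return _nri_from_dm(dm, comm_idx, config, _resolve_seed(config))


def nri_profile(
    tree: dendropy.Tree, matrix: BeltMatrix, config: NullModelConfig | None = None
) -> pd.DataFrame:
    """NRI for every belt of a matched tree/matrix pair.

    The pool defaults to all taxa of the matrix (the mountain's recorded
    flora). Belts with fewer than two taxa are reported with ``evaluable =
    False`` and NaN statistics. Per-belt seeds are derived deterministically
    from the configured seed, so the whole profile is reproducible.
    """
    config = config or NullModelConfig()
    if set(tip_labels(tree)) != set(matrix.taxa):
        raise ValueError("tree and matrix taxa differ; run match_tree_matrix first")
    pool = sorted(config.pool) if config.pool is not None else sorted(matrix.taxa)
    dm = patristic_distance_matrix(tree, pool)
    pos = {t: i for i, t in enumerate(pool)}
    base_seed = _resolve_seed(config)
    seed_seq = np.random.SeedSequence(base_seed)
    belt_seeds = [int(s) for s in seed_seq.generate_state(matrix.grid.n_belts)]

    rows = []
    for i, (lo, hi) in enumerate(matrix.grid.belts):
        taxa = matrix.belt_taxa(i)
        row = {
            "belt_lo": lo,
            "belt_hi": hi,
            "midpoint": (lo + hi) / 2.0,
            "n_taxa": len(taxa),
            "evaluable": len(taxa) >= 2,
            "mpd_obs": math.nan,
            "null_mean": math.nan,
            "null_sd": math.nan,
            "nri": math.nan,
            "rank_p": math.nan,
            "scheme": config.scheme,
            "n_reps": config.n_reps,
            "seed": base_seed,
        }
        if len(taxa) >= 2:
            comm_idx = np.array(sorted(pos[t] for t in taxa))
            res = _nri_from_dm(dm, comm_idx, config, belt_seeds[i] % 2**31)
            row.update(
                mpd_obs=res.mpd_obs, null_mean=res.null_mean, null_sd=res.null_sd,
                nri=res.nri, rank_p=res.rank_p, evaluable=not res.degenerate,
            )
        rows.append(row)
    n_eval = sum(r["evaluable"] for r in rows)
    if n_eval == 0:
        logger.warning("no belt had >= 2 taxa; NRI profile is empty of evaluable belts")
    return pd.DataFrame(rows)
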