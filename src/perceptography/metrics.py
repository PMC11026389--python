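"""Quantitative instruments for campaign analysis.

Fréchet feature distance between Gaussian fits of feature-vector sets (with
optional per-class max normalization), pixel RMSE, motion energy of stimulus
sequences, Welch's t-test, the permutation-style bootstrap null for the
family-selection procedure, convergence curves, and the evolution dendrogram.
All functions are pure; the only stateful object is the explicit class-max
registry used by the normalized distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError
from .image_space import ImageRaster
from .trials import OUTCOME_FA, TrialRecord

__all__ = [
    "FeatureSet",
    "DendrogramNode",
    "ClassMaxRegistry",
    "frechet_distance",
    "normalized_frechet",
    "normalized_frechet_two_pass",
    "singleton_feature_set",
    "pixel_rmse",
    "motion_energy",
    "welch_t",
    "bootstrap_family_null",
    "enumerate_family_null",
    "empirical_p_value",
    "convergence_curve",
    "build_dendrogram",
]


@dataclass
class FeatureSet:
    """Matrix of feature vectors: rows are images, columns feature dims."""

    features: np.ndarray
    extractor_id: str = ""

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if not np.all(np.isfinite(self.features)):
            raise ParameterError("features: entries must be finite")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


def singleton_feature_set(
    vector: np.ndarray, n: int = 16, scale: float = 1e-3, seed: int = 0,
    extractor_id: str = "",
) -> FeatureSet:
    """Expand one feature vector into a tight deterministic cloud.

    Gaussian-fit distances need at least two rows; a single image is
    represented by its vector plus isotropic jitter of negligible scale so
    the mean term dominates any distance computed against it.
    """
    v = np.asarray(vector, dtype=float).ravel()
    rng = np.random.Generator(np.random.PCG64(seed))
    pts = v[None, :] + scale * rng.standard_normal((n, v.size))
    return FeatureSet(features=pts, extractor_id=extractor_id)


def _gaussian_fit(fs: FeatureSet, eps_rel: float) -> tuple[np.ndarray, np.ndarray]:
    x = fs.features
    mu = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    # small sample sets in many dims are rank-deficient; ridge keeps the
    # matrix square root well-defined
    eps = eps_rel * np.trace(cov) / cov.shape[0]
    cov = cov + eps * np.eye(cov.shape[0])
    return mu, cov


def frechet_distance(a: FeatureSet, b: FeatureSet, eps_rel: float = 1e-6) -> float:
    """Fréchet distance between Gaussian fits of two feature sets.

    ||mu_a - mu_b||^2 + Tr(Sigma_a + Sigma_b - 2 (Sigma_a Sigma_b)^{1/2}),
    with the covariance product's square root taken through a symmetric
    eigendecomposition (negative eigenvalues clipped at zero).  Symmetric,
    non-negative, and zero for sets with identical first two moments.
    """
    if a.n < 2 or b.n < 2:
        raise ParameterError("feature sets need >= 2 rows for a covariance fit")
    if a.dim != b.dim:
        raise ParameterError(f"feature dims differ: {a.dim} vs {b.dim}")
    mu_a, cov_a = _gaussian_fit(a, eps_rel)
    mu_b, cov_b = _gaussian_fit(b, eps_rel)
    # Tr((Sigma_a Sigma_b)^{1/2}) through the symmetric form
    # Sigma_a^{1/2} Sigma_b Sigma_a^{1/2}: same eigenvalues as the plain
    # product but an explicitly symmetric eigenproblem, so clipping tiny
    # negative eigenvalues is safe
    wa, va = np.linalg.eigh(cov_a)
    sqrt_a = (va * np.sqrt(np.clip(wa, 0.0, None))) @ va.T
    inner = sqrt_a @ cov_b @ sqrt_a
    eigvals = np.linalg.eigvalsh(0.5 * (inner + inner.T))
    tr_sqrt = np.sum(np.sqrt(np.clip(eigvals, 0.0, None)))
    diff = mu_a - mu_b
    d = float(diff @ diff + np.trace(cov_a) + np.trace(cov_b) - 2.0 * tr_sqrt)
    return max(d, 0.0)


class ClassMaxRegistry:
    """Running per-class maxima used to normalize raw Fréchet distances.

    Maxima never decrease.  Streaming normalization divides by the max known
    at computation time (including the value being normalized); the two-pass
    helper below recomputes everything against the global max and is the
    default for reported figures.
    """

    def __init__(self) -> None:
        self._max: dict = {}

    def observe(self, class_id, value: float) -> float:
        if value < 0:
            raise ParameterError("value: raw distances are non-negative")
        cur = self._max.get(class_id, 0.0)
        if value > cur:
            self._max[class_id] = value
            cur = value
        return cur

    def maximum(self, class_id) -> float:
        if class_id not in self._max:
            raise ParameterError(
                f"class {class_id!r} has no registered maximum; call "
                "registry.observe(class_id, raw) to initialize it"
            )
        return self._max[class_id]

    def as_dict(self) -> dict:
        return dict(self._max)


def normalized_frechet(
    a: FeatureSet, b: FeatureSet, class_id, registry: ClassMaxRegistry,
) -> float:
    """Raw Fréchet distance divided by the running class maximum (streaming)."""
    raw = frechet_distance(a, b)
    m = registry.observe(class_id, raw)
    if m <= 0:
        return 0.0
    return raw / m


def normalized_frechet_two_pass(
    raw_values: Sequence[float], class_ids: Sequence | None = None
) -> np.ndarray:
    """Two-pass (global class max) normalization — the reporting default."""
    raw = np.asarray(raw_values, dtype=float)
    if class_ids is None:
        class_ids = [0] * raw.size
    out = np.empty_like(raw)
    for cid in set(class_ids):
        mask = np.array([c == cid for c in class_ids])
        m = raw[mask].max()
        out[mask] = raw[mask] / m if m > 0 else 0.0
    return out


def pixel_rmse(a: ImageRaster | np.ndarray, b: ImageRaster | np.ndarray) -> float:
    """Square root of the mean squared difference of corresponding pixels."""
    pa = a.pixels if isinstance(a, ImageRaster) else np.asarray(a, dtype=float)
    pb = b.pixels if isinstance(b, ImageRaster) else np.asarray(b, dtype=float)
    if pa.shape != pb.shape:
        raise ParameterError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    return float(np.sqrt(np.mean((pa - pb) ** 2)))


def motion_energy(frames: Sequence[ImageRaster | np.ndarray]) -> float:
    """Summed mean-squared pixel difference over consecutive frame pairs."""
    if len(frames) < 2:
        raise ParameterError("frames: need at least 2 frames")
    arrs = [
        f.pixels if isinstance(f, ImageRaster) else np.asarray(f, dtype=float)
        for f in frames
    ]
    total = 0.0
    for f0, f1 in zip(arrs[:-1], arrs[1:]):
        if f0.shape != f1.shape:
            raise ParameterError("frames: shape mismatch within sequence")
        total += float(np.mean((f1 - f0) ** 2))
    return total


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's t statistic, Welch–Satterthwaite df, and two-sided p."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("samples: need >= 2 values each")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va <= 0 and vb <= 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ParameterError("samples: zero variance with unequal means")
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# bootstrap null for the family-selection procedure


def _family_slots(
    records: Sequence[TrialRecord], family_members: Mapping[str, Iterable[str]]
) -> tuple[np.ndarray, int, np.ndarray, list]:
    """Map completed non-stimulated presentations onto family indices."""
    member_to_family: dict[str, int] = {}
    family_ids = list(family_members)
    for fi, fid in enumerate(family_ids):
        for img in family_members[fid]:
            member_to_family[img] = fi
    slot_family = []
    n_fa = 0
    for r in records:
        if r.stimulated or r.outcome == "aborted":
            continue
        slot_family.append(member_to_family.get(r.image_id, -1))
        if r.outcome == OUTCOME_FA:
            n_fa += 1
    slot_family = np.asarray(slot_family, dtype=int)
    fam_sizes = np.array(
        [(slot_family == fi).sum() for fi in range(len(family_ids))], dtype=int
    )
    return slot_family, n_fa, fam_sizes, family_ids


def _max_family_rate(fa_per_family: np.ndarray, fam_sizes: np.ndarray) -> float:
    valid = fam_sizes > 0
    if not np.any(valid):
        raise ParameterError("families: no family has non-stimulated presentations")
    return float(np.max(fa_per_family[valid] / fam_sizes[valid]))


def bootstrap_family_null(
    records: Sequence[TrialRecord],
    family_members: Mapping[str, Iterable[str]],
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null distribution of the maximum cumulative family FA rate.

    Each replicate keeps the observed total number of false alarms but
    reassigns them uniformly at random (without replacement) across all
    completed non-stimulated presentations, then records the maximum pooled
    FA rate over the given families.  This is the "what if the animal's
    false alarms carried no image information" null.
    """
    if n_boot < 1:
        raise ParameterError("n_boot: must be >= 1")
    slot_family, n_fa, fam_sizes, _ = _family_slots(records, family_members)
    if n_fa < 1:
        raise ParameterError("records: need at least one false alarm")
    n_slots = slot_family.size
    n_fam = fam_sizes.size
    maxima = np.empty(n_boot)
    for i in range(n_boot):
        hit_slots = rng.choice(n_slots, size=n_fa, replace=False)
        fams = slot_family[hit_slots]
        fa_per_family = np.bincount(fams[fams >= 0], minlength=n_fam)
        maxima[i] = _max_family_rate(fa_per_family, fam_sizes)
    return maxima


def enumerate_family_null(
    records: Sequence[TrialRecord],
    family_members: Mapping[str, Iterable[str]],
) -> dict[float, float]:
    """Exact null distribution by exhaustive enumeration of FA placements.

    Feasible for toy instances (use for <= ~8 non-stimulated presentations);
    serves as the independent oracle for the Monte-Carlo bootstrap.
    """
    slot_family, n_fa, fam_sizes, _ = _family_slots(records, family_members)
    n_slots = slot_family.size
    n_fam = fam_sizes.size
    dist: dict[float, float] = {}
    combos = list(itertools.combinations(range(n_slots), n_fa))
    for hit in combos:
        fams = slot_family[list(hit)]
        fa_per_family = np.bincount(fams[fams >= 0], minlength=n_fam)
        m = _max_family_rate(fa_per_family, fam_sizes)
        dist[m] = dist.get(m, 0.0) + 1.0
    total = len(combos)
    return {k: v / total for k, v in sorted(dist.items())}


def empirical_p_value(null_maxima: np.ndarray, observed: float) -> float:
    """Fraction of null maxima at or above the observed statistic."""
    null_maxima = np.asarray(null_maxima, dtype=float)
    return float(np.mean(null_maxima >= observed))


# ---------------------------------------------------------------------------
# convergence curve and dendrogram


def convergence_curve(
    iteration_pools: Sequence[FeatureSet | None],
    winner_reference: FeatureSet,
) -> list[float | None]:
    """Per-iteration Fréchet distance from the pool to the winner reference.

    Callers exclude the winner's own family from each pool before building
    the per-iteration feature sets; an iteration whose pool is empty after
    exclusion is reported as None (missing).
    """
    if len(iteration_pools) < 1:
        raise ParameterError("iteration_pools: need at least one iteration")
    out: list[float | None] = []
    for pool in iteration_pools:
        if pool is None or pool.n < 2:
            out.append(None)
        else:
            out.append(frechet_distance(pool, winner_reference))
    return out


@dataclass
class DendrogramNode:
    """One image in the evolution dendrogram."""

    image_id: str
    parent: str | None
    iteration: int
    fid_to_seed: float
    fa_rate: float | None


def build_dendrogram(
    families,
    scores: Mapping[str, "object"],
    fid_to_seed: Mapping[str, float],
) -> list[DendrogramNode]:
    """Flatten image families into dendrogram nodes.

    ``families`` is an iterable of objects with ``members`` mapping image_id
    to {"parent": id|None, "iteration": int}; ``fid_to_seed`` gives each
    image's feature distance from its seed; branch thickness is the FA rate.
    """
    nodes: list[DendrogramNode] = []
    for fam in families:
        for image_id, info in fam.members.items():
            parent = info["parent"]
            if parent is not None and parent not in fam.members:
                raise ParameterError(
                    f"orphan member {image_id}: parent {parent} not in family"
                )
            sc = scores.get(image_id)
            nodes.append(
                DendrogramNode(
                    image_id=image_id,
                    parent=parent,
                    iteration=int(info["iteration"]),
                    fid_to_seed=float(fid_to_seed.get(image_id, 0.0)),
                    fa_rate=None if sc is None else sc.fa_rate,
                )
            )
    return nodes


def dendrogram_to_graph(nodes: Sequence[DendrogramNode]):
    """Dendrogram as a networkx DiGraph (edges parent -> child)."""
    import networkx as nx

    g = nx.DiGraph()
    for n in nodes:
        g.add_node(
            n.image_id,
            iteration=n.iteration,
            fid_to_seed=n.fid_to_seed,
            fa_rate=-1.0 if n.fa_rate is None else n.fa_rate,
        )
    for n in nodes:
        if n.parent is not None:
            g.add_edge(n.parent, n.image_id)
    return g


def export_dendrogram_edgelist(nodes: Sequence[DendrogramNode], path) -> None:
    """Tab-separated edge list: child, parent, iteration, fid_to_seed, fa_rate."""
    with open(path, "w") as fh:
        fh.write("image_id\tparent\titeration\tfid_to_seed\tfa_rate\n")
        for n in nodes:
            fa = "" if n.fa_rate is None else f"{n.fa_rate:.6f}"
            parent = "" if n.parent is None else n.parent
            fh.write(f"{n.image_id}\t{parent}\t{n.iteration}\t{n.fid_to_seed:.6f}\t{fa}\n")


def import_dendrogram_edgelist(path) -> list[DendrogramNode]:
    nodes = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("image_id"):
            raise ParameterError("edge list: unexpected header")
        for line in fh:
            image_id, parent, iteration, fid, fa = line.rstrip("\n").split("\t")
            nodes.append(
                DendrogramNode(
                    image_id=image_id,
                    parent=parent or None,
                    iteration=int(iteration),
                    fid_to_seed=float(fid),
                    fa_rate=float(fa) if fa else None,
                )
            )
    return nodes


def render_dendrogram_svg(nodes: Sequence[DendrogramNode], path) -> None:
    """Draw the dendrogram (x: iteration, y: feature distance to seed,
    line width proportional to FA rate) and save as SVG."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    by_id = {n.image_id: n for n in nodes}
    fig, ax = plt.subplots(figsize=(7, 5))
    for n in nodes:
        fa = 0.0 if n.fa_rate is None else n.fa_rate
        ax.scatter(n.iteration, n.fid_to_seed, s=12 + 60 * fa, color="tab:blue", zorder=3)
        if n.parent is not None and n.parent in by_id:
            p = by_id[n.parent]
            ax.plot(
                [p.iteration, n.iteration],
                [p.fid_to_seed, n.fid_to_seed],
                lw=0.5 + 4.0 * fa,
                color="tab:blue",
                alpha=0.6,
            )
    ax.set_xlabel("iteration")
    ax.set_ylabel("feature distance to seed")
    fig.savefig(path, format="svg")
    plt.close(fig)
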