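"""Binary grey-wolf wrapper feature selection with a KNN cross-validation
fitness, plus a binary PSO and a random-search baseline for convergence
comparison.

The optimizer follows the canonical grey-wolf dynamics: the three best-ever
distinct solutions (alpha, beta, delta) attract every wolf through the
update ``A = a (2 r1 - 1)``, ``C = 2 r2``, ``D = |C x_L - x|``,
``X_L = x_L - A D``, candidate = mean of the three pulled positions, with
the exploration parameter ``a`` decaying linearly from 2 to 0 across
iterations.  Positions are continuous and retained between iterations;
feature masks are obtained bitwise through a sigmoid transfer
``S(v) = 1 / (1 + exp(-lambda (v - 0.5)))`` compared against a uniform
draw.  A wolf that selects no features is repaired to a uniformly random
subset of size 1..init_k.

Fitness is the mean stratified 5-fold cross-validation accuracy of a
k-nearest-neighbour classifier restricted to the selected columns — pure
accuracy, no feature-count penalty; parsimony enters only through leader
tie-breaking (fewer selected features win exact fitness ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .features import FeatureMatrix

__all__ = [
    "FeatureMask",
    "EGWOConfig",
    "EGWOResult",
    "init_population",
    "fitness_knn_cv",
    "repair",
    "update_positions",
    "run_egwo",
    "run_bpso",
    "run_random_search",
]


@dataclass
class FeatureMask:
    """A candidate feature subset ("wolf"): a binary inclusion vector with an
    attached fitness, plus the continuous position the binary vector was
    transferred from (kept so the search dynamics stay well defined)."""

    bits: np.ndarray
    fitness: float | None = None
    position: np.ndarray | None = None

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.position is None:
            self.position = self.bits.astype(float)
        else:
            self.position = np.asarray(self.position, dtype=float)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def copy(self) -> "FeatureMask":
        return FeatureMask(self.bits.copy(), self.fitness,
                           self.position.copy())


@dataclass(frozen=True)
class EGWOConfig:
    num_wolves: int = 30
    max_iter: int = 100
    init_k: int = 30          # selected features per wolf at initialization
    knn_k: int = 5
    cv_folds: int = 5
    a_start: float = 2.0
    a_end: float = 0.0
    transfer_steepness: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.num_wolves < 3:
            raise ValueError("need at least 3 wolves (alpha, beta, delta)")
        if self.init_k < 1:
            raise ValueError("init_k must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")


@dataclass
class EGWOResult:
    best_mask: FeatureMask
    convergence: np.ndarray            # best-so-far fitness per iteration
    n_evaluations: int = 0
    leaders_history: list | None = None


def a_schedule(iteration: int, cfg: EGWOConfig) -> float:
    """Exploration parameter ``a``: linear decay a_start -> a_end over the
    run (reaches a_end exactly on the final iteration)."""
    if cfg.max_iter <= 1:
        return cfg.a_end if cfg.max_iter == 1 else cfg.a_start
    frac = iteration / (cfg.max_iter - 1)
    return cfg.a_start + (cfg.a_end - cfg.a_start) * frac


def init_population(d: int, cfg: EGWOConfig,
                    rng: np.random.Generator | None = None) -> list[FeatureMask]:
    """num_wolves masks, each with exactly ``min(init_k, d)`` bits set,
    chosen uniformly without replacement; reproducible from the config seed."""
    if d < 1:
        raise ValueError("feature dimension must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    k = min(cfg.init_k, d)
    wolves = []
    for _ in range(cfg.num_wolves):
        bits = np.zeros(d, dtype=bool)
        bits[rng.choice(d, size=k, replace=False)] = True
        wolves.append(FeatureMask(bits))
    return wolves


def fitness_knn_cv(mask: FeatureMask, fm: FeatureMatrix,
                   cfg: EGWOConfig) -> float:
    """Mean stratified k-fold CV accuracy of KNN on the selected columns.

    Fold assignment is derived from the config seed, so a fitness value is a
    deterministic function of (data, mask, config).
    """
    if mask.popcount < 1:
        raise ValueError("empty mask: repair before evaluating fitness")
    counts = np.bincount(fm.labels)
    smallest = counts[counts > 0].min()
    if smallest < cfg.cv_folds:
        raise ValueError(
            f"smallest class has {smallest} members; need >= {cfg.cv_folds} "
            "for stratified CV"
        )
    X = fm.values[:, mask.bits]
    y = fm.labels
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                          random_state=cfg.seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        clf = KNeighborsClassifier(n_neighbors=cfg.knn_k)
        clf.fit(X[train_idx], y[train_idx])
        accs.append(float(np.mean(clf.predict(X[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def repair(mask: FeatureMask, cfg: EGWOConfig,
           rng: np.random.Generator) -> FeatureMask:
    """Replace a degenerate all-zero mask with a uniformly random subset of
    size drawn uniformly from {1..min(init_k, d)}; nonzero masks pass
    through unchanged."""
    if mask.popcount > 0:
        return mask
    d = mask.bits.size
    k = int(rng.integers(1, min(cfg.init_k, d) + 1))
    bits = np.zeros(d, dtype=bool)
    bits[rng.choice(d, size=k, replace=False)] = True
    return FeatureMask(bits)


def _sigmoid_transfer(v: np.ndarray, steepness: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-steepness * (v - 0.5)))


def update_positions(wolves: list[FeatureMask], alpha: FeatureMask,
                     beta: FeatureMask, delta: FeatureMask, a: float,
                     cfg: EGWOConfig,
                     rng: np.random.Generator) -> list[FeatureMask]:
    """One grey-wolf position update for every wolf, followed by sigmoid
    binarization and repair."""
    d = wolves[0].bits.size
    leaders = [alpha, beta, delta]
    out = []
    for w in wolves:
        x = w.position
        pulled = []
        for L in leaders:
            r1 = rng.random(d)
            r2 = rng.random(d)
            A = a * (2.0 * r1 - 1.0)
            C = 2.0 * r2
            D = np.abs(C * L.position - x)
            pulled.append(L.position - A * D)
        candidate = (pulled[0] + pulled[1] + pulled[2]) / 3.0
        r3 = rng.random(d)
        bits = _sigmoid_transfer(candidate, cfg.transfer_steepness) > r3
        out.append(repair(FeatureMask(bits, position=candidate), cfg, rng))
    return out


def _leader_key(entry):
    # Maximize fitness; break exact ties toward fewer selected features,
    # then toward the earlier-evaluated wolf.
    fitness, popcount, order, _ = entry
    return (-fitness, popcount, order)


class _LeaderArchive:
    """Best-ever distinct masks, ranked by (fitness desc, popcount, order)."""

    def __init__(self):
        self._entries: list = []
        self._seen: set = set()
        self._counter = 0

    def offer(self, mask: FeatureMask) -> None:
        key = mask.bits.tobytes()
        if key in self._seen:
            return
        self._seen.add(key)
        self._entries.append((mask.fitness, mask.popcount, self._counter,
                              mask.copy()))
        self._counter += 1
        self._entries.sort(key=_leader_key)
        del self._entries[8:]   # keep a small head; only top 3 are used

    def top3(self) -> tuple[FeatureMask, FeatureMask, FeatureMask]:
        top = [e[3] for e in self._entries[:3]]
        while len(top) < 3:       # fewer than 3 distinct masks seen so far
            top.append(top[-1])
        return top[0], top[1], top[2]


def run_egwo(fm: FeatureMatrix, cfg: EGWOConfig,
             track_leaders: bool = False) -> EGWOResult:
    """Full wrapper-selection run.

    Every wolf is evaluated once per iteration plus once at initialization
    (exactly ``num_wolves * (max_iter + 1)`` fitness evaluations); leaders
    are elitist best-ever distinct wolves, so the best-so-far curve is
    nondecreasing by construction.
    """
    if np.unique(fm.labels).size < 2:
        raise ValueError("feature selection requires at least 2 classes")
    rng = np.random.default_rng(cfg.seed)
    d = fm.n_features
    wolves = init_population(d, cfg, rng)
    archive = _LeaderArchive()
    n_eval = 0
    for w in wolves:
        w.fitness = fitness_knn_cv(w, fm, cfg)
        n_eval += 1
        archive.offer(w)
    convergence = []
    history = [] if track_leaders else None
    for t in range(cfg.max_iter):
        alpha, beta, delta = archive.top3()
        a = a_schedule(t, cfg)
        wolves = update_positions(wolves, alpha, beta, delta, a, cfg, rng)
        for w in wolves:
            w.fitness = fitness_knn_cv(w, fm, cfg)
            n_eval += 1
            archive.offer(w)
        best = archive.top3()[0]
        convergence.append(best.fitness)
        if track_leaders:
            history.append(tuple(m.copy() for m in archive.top3()))
    best = archive.top3()[0]
    return EGWOResult(best_mask=best, convergence=np.array(convergence),
                      n_evaluations=n_eval, leaders_history=history)


def run_bpso(fm: FeatureMatrix, cfg: EGWOConfig) -> EGWOResult:
    """Binary particle swarm baseline sharing the fitness function,
    population size, iteration budget and sigmoid transfer, for
    convergence-curve comparison."""
    if np.unique(fm.labels).size < 2:
        raise ValueError("feature selection requires at least 2 classes")
    rng = np.random.default_rng(cfg.seed)
    d = fm.n_features
    particles = init_population(d, cfg, rng)
    velocity = np.zeros((cfg.num_wolves, d))
    n_eval = 0
    for p in particles:
        p.fitness = fitness_knn_cv(p, fm, cfg)
        n_eval += 1
    pbest = [p.copy() for p in particles]
    gbest = max(pbest, key=lambda m: (m.fitness, -m.popcount)).copy()
    c1 = c2 = 2.0
    convergence = []
    for t in range(cfg.max_iter):
        w_inertia = 0.9 - 0.5 * (t / max(cfg.max_iter - 1, 1))
        for i, p in enumerate(particles):
            r1 = rng.random(d)
            r2 = rng.random(d)
            velocity[i] = (w_inertia * velocity[i]
                           + c1 * r1 * (pbest[i].position - p.position)
                           + c2 * r2 * (gbest.position - p.position))
            pos = np.clip(p.position + velocity[i], -2.0, 3.0)
            r3 = rng.random(d)
            bits = _sigmoid_transfer(pos, cfg.transfer_steepness) > r3
            cand = repair(FeatureMask(bits, position=pos), cfg, rng)
            cand.fitness = fitness_knn_cv(cand, fm, cfg)
            n_eval += 1
            particles[i] = cand
            if (cand.fitness, -cand.popcount) > (pbest[i].fitness,
                                                 -pbest[i].popcount):
                pbest[i] = cand.copy()
            if (cand.fitness, -cand.popcount) > (gbest.fitness,
                                                 -gbest.popcount):
                gbest = cand.copy()
        convergence.append(gbest.fitness)
    return EGWOResult(best_mask=gbest, convergence=np.array(convergence),
                      n_evaluations=n_eval)


def run_random_search(fm: FeatureMatrix, cfg: EGWOConfig) -> EGWOResult:
    """Budget-matched random search: ``num_wolves * (max_iter + 1)`` masks
    drawn like the initial population, tracking the best seen."""
    if np.unique(fm.labels).size < 2:
        raise ValueError("feature selection requires at least 2 classes")
    rng = np.random.default_rng(cfg.seed)
    d = fm.n_features
    budget = cfg.num_wolves * (cfg.max_iter + 1)
    best = None
    convergence = []
    for i in range(budget):
        k = int(rng.integers(1, min(cfg.init_k, d) + 1))
        bits = np.zeros(d, dtype=bool)
        bits[rng.choice(d, size=k, replace=False)] = True
        m = FeatureMask(bits)
        m.fitness = fitness_knn_cv(m, fm, cfg)
        if best is None or (m.fitness, -m.popcount) > (best.fitness,
                                                       -best.popcount):
            best = m.copy()
        if (i + 1) % cfg.num_wolves == 0:
            convergence.append(best.fitness)
    return EGWOResult(best_mask=best, convergence=np.array(convergence),
                      n_evaluations=budget)
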