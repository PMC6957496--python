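"""NSGA-II search over the classifier's architecture hyperparameters.

The genome covers, for each of the six conv blocks (two per morphology path,
two for the timing path), the subsampling stride and filter count on
log2-spaced grids with the convolution width linear, plus the dense-layer
width, L2 penalty (log-spaced) and dropout fraction.  Fitness is validation
accuracy of a network trained from the genes; an un-buildable gene
combination scores 0.  NSGA-II runs with accuracy as the single objective by
default; parameter count can be enabled as a second (minimized) objective to
let the algorithm also hunt small networks.  Identical genomes are cached so
no architecture is ever trained twice within one search.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network import (ConvBlockSpec, NetworkConfig, TrainConfig, build_network,
                      train, _accuracy, _as_arrays)

__all__ = ["SearchSpace", "GaConfig", "decode_genes", "evaluate_individual",
           "run_search"]


@dataclass(frozen=True)
class GeneBound:
    low: float
    high: float
    kind: str  # "int" | "log2int" | "float" | "logfloat"

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("gene bound must have low <= high")


@dataclass(frozen=True)
class SearchSpace:
    """Per-gene bounds; defaults envelope every published architecture row."""

    subsampling: tuple = (1, 32)
    convolution_width: tuple = (5, 300)
    filters: tuple = (4, 64)
    dense_units: tuple = (32, 1024)
    l2_lambda: tuple = (1e-5, 1e-2)
    dropout: tuple = (0.0, 0.5)

    def bounds(self) -> list[GeneBound]:
        out: list[GeneBound] = []
        for _block in range(6):  # 2 morph paths x 2 + timing x 2
            out.append(GeneBound(np.log2(self.subsampling[0]),
                                 np.log2(self.subsampling[1]), "log2int"))
            out.append(GeneBound(*self.convolution_width, "int"))
            out.append(GeneBound(np.log2(self.filters[0]),
                                 np.log2(self.filters[1]), "log2int"))
        out.append(GeneBound(np.log2(self.dense_units[0]),
                             np.log2(self.dense_units[1]), "log2int"))
        out.append(GeneBound(np.log10(self.l2_lambda[0]),
                             np.log10(self.l2_lambda[1]), "logfloat"))
        out.append(GeneBound(*self.dropout, "float"))
        return out


@dataclass(frozen=True)
class GaConfig:
    population_size: int = 20
    generations: int = 10
    inner_epochs: int = 50
    inner_patience: int = 3
    seed: int = 0
    crossover_prob: float = 0.9
    crossover_eta: float = 15.0
    mutation_eta: float = 20.0
    minimize_size: bool = False  # optional second objective: parameter count
    batch_size: int = 100
    learning_rate: float = 0.0001

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population must be >= 2")
        if self.generations < 1:
            raise ValueError("need at least one generation")


def _gene_value(x: float, b: GeneBound):
    x = float(np.clip(x, b.low, b.high))
    if b.kind == "int":
        return int(round(x))
    if b.kind == "log2int":
        return int(round(2.0 ** round(x)))
    if b.kind == "logfloat":
        return float(10.0 ** x)
    return x


def decode_genes(genes: np.ndarray, space: SearchSpace,
                 base: NetworkConfig | None = None) -> NetworkConfig:
    """Map a genome to a NetworkConfig (input widths come from ``base``)."""
    base = base or NetworkConfig()
    bounds = space.bounds()
    vals = [_gene_value(g, b) for g, b in zip(genes, bounds)]
    blocks = [ConvBlockSpec(vals[3 * i], vals[3 * i + 1], vals[3 * i + 2])
              for i in range(6)]
    return replace(
        base,
        morph_path_1=(blocks[0], blocks[1]),
        morph_path_2=(blocks[2], blocks[3]),
        timing_path=(blocks[4], blocks[5]),
        dense_units=vals[18],
        l2_lambda=vals[19],
        dropout=vals[20],
    )


def evaluate_individual(genes: np.ndarray, train_set, val_set,
                        ga_cfg: GaConfig | None = None,
                        space: SearchSpace | None = None,
                        base: NetworkConfig | None = None) -> float:
    """Validation accuracy (%) of a network built from ``genes``.

    Training uses the inner-loop preset: up to ``inner_epochs`` epochs with
    early stopping once training accuracy stalls for ``inner_patience``
    epochs.  Gene combinations that cannot be built score 0.
    """
    ga_cfg = ga_cfg or GaConfig()
    space = space or SearchSpace()
    try:
        cfg = decode_genes(np.asarray(genes, dtype=float), space, base)
        model = build_network(cfg, seed=ga_cfg.seed)
    except (ValueError, MemoryError):
        return 0.0
    tc = TrainConfig(learning_rate=ga_cfg.learning_rate,
                     batch_size=ga_cfg.batch_size, epochs=ga_cfg.inner_epochs,
                     early_stop_patience=ga_cfg.inner_patience, seed=ga_cfg.seed)
    train(model, train_set, None, tc)
    vm, vt, vy = _as_arrays(val_set)
    return _accuracy(model, vm, vt, np.asarray(vy, dtype=int))


@dataclass
class SearchResult:
    best_genes: np.ndarray
    best_fitness: float
    best_config: NetworkConfig
    history: list[dict] = field(default_factory=list)  # per-generation best/mean
    evaluations: int = 0


# -- NSGA-II machinery -------------------------------------------------------


def _fast_non_dominated_sort(objs: np.ndarray) -> list[list[int]]:
    """Rank rows of a (n, m) minimization objective matrix into fronts."""
    n = len(objs)
    dominates = [[] for _ in range(n)]
    dominated_by = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if np.all(objs[i] <= objs[j]) and np.any(objs[i] < objs[j]):
                dominates[i].append(j)
                dominated_by[j] += 1
            elif np.all(objs[j] <= objs[i]) and np.any(objs[j] < objs[i]):
                dominates[j].append(i)
                dominated_by[i] += 1
    fronts = [[i for i in range(n) if dominated_by[i] == 0]]
    while fronts[-1]:
        nxt = []
        for i in fronts[-1]:
            for j in dominates[i]:
                dominated_by[j] -= 1
                if dominated_by[j] == 0:
                    nxt.append(j)
        fronts.append(nxt)
    return fronts[:-1]


def _crowding(objs: np.ndarray, front: list[int]) -> np.ndarray:
    dist = np.zeros(len(front))
    sub = objs[front]
    for m in range(objs.shape[1]):
        order = np.argsort(sub[:, m])
        span = sub[order[-1], m] - sub[order[0], m]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            for k in range(1, len(front) - 1):
                dist[order[k]] += (sub[order[k + 1], m] - sub[order[k - 1], m]) / span
    return dist


def _sbx(p1: np.ndarray, p2: np.ndarray, bounds, eta: float,
         rng: np.random.Generator):
    """Simulated binary crossover, per-gene."""
    c1, c2 = p1.copy(), p2.copy()
    for i, b in enumerate(bounds):
        if rng.random() > 0.5 or abs(p1[i] - p2[i]) < 1e-14:
            continue
        u = rng.random()
        beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else \
            (1 / (2 * (1 - u))) ** (1 / (eta + 1))
        c1[i] = np.clip(0.5 * ((1 + beta) * p1[i] + (1 - beta) * p2[i]), b.low, b.high)
        c2[i] = np.clip(0.5 * ((1 - beta) * p1[i] + (1 + beta) * p2[i]), b.low, b.high)
    return c1, c2


def _polynomial_mutation(x: np.ndarray, bounds, eta: float, prob: float,
                         rng: np.random.Generator) -> np.ndarray:
    y = x.copy()
    for i, b in enumerate(bounds):
        if rng.random() >= prob or b.high <= b.low:
            continue
        u = rng.random()
        span = b.high - b.low
        if u < 0.5:
            delta = (2 * u) ** (1 / (eta + 1)) - 1
        else:
            delta = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
        y[i] = np.clip(y[i] + delta * span, b.low, b.high)
    return y


def _gene_key(genes: np.ndarray, space: SearchSpace,
              base: NetworkConfig | None) -> tuple:
    cfg = decode_genes(genes, space, base)
    return (cfg.morph_path_1, cfg.morph_path_2, cfg.timing_path,
            cfg.dense_units, round(cfg.l2_lambda, 8), round(cfg.dropout, 4))


def run_search(space: SearchSpace, cfg: GaConfig, train_set, val_set,
               base: NetworkConfig | None = None) -> SearchResult:
    """NSGA-II loop; returns the best individual and the fitness trajectory.

    Elitism (mu+lambda survival over the combined parent+offspring pool)
    guarantees the generation-best fitness never decreases.
    """
    bounds = space.bounds()
    rng = np.random.default_rng(cfg.seed)
    n_genes = len(bounds)
    mut_prob = 1.0 / n_genes
    cache: dict[tuple, float] = {}
    result = SearchResult(best_genes=np.empty(0), best_fitness=-1.0,
                          best_config=base or NetworkConfig())

    def fitness(genes: np.ndarray) -> float:
        key = _gene_key(genes, space, base)
        if key not in cache:
            result.evaluations += 1
            cache[key] = evaluate_individual(genes, train_set, val_set, cfg,
                                             space, base)
        return cache[key]

    def objectives(genes: np.ndarray, acc: float) -> np.ndarray:
        if not cfg.minimize_size:
            return np.array([-acc])
        try:
            n_par = build_network(decode_genes(genes, space, base)).num_params
        except ValueError:
            n_par = np.inf
        return np.array([-acc, float(n_par)])

    pop = [np.array([rng.uniform(b.low, b.high) for b in bounds])
           for _ in range(cfg.population_size)]
    accs = [fitness(g) for g in pop]

    for _gen in range(cfg.generations):
        objs = np.stack([objectives(g, a) for g, a in zip(pop, accs)])
        fronts = _fast_non_dominated_sort(objs)
        rank = np.empty(len(pop), dtype=int)
        crowd = np.empty(len(pop))
        for r, front in enumerate(fronts):
            rank[front] = r
            crowd[front] = _crowding(objs, front)

        def tourney() -> np.ndarray:
            i, j = rng.integers(0, len(pop), size=2)
            if rank[i] < rank[j] or (rank[i] == rank[j] and crowd[i] > crowd[j]):
                return pop[i]
            return pop[j]

        children: list[np.ndarray] = []
        while len(children) < cfg.population_size:
            p1, p2 = tourney(), tourney()
            if rng.random() < cfg.crossover_prob:
                c1, c2 = _sbx(p1, p2, bounds, cfg.crossover_eta, rng)
            else:
                c1, c2 = p1.copy(), p2.copy()
            children.append(_polynomial_mutation(c1, bounds, cfg.mutation_eta,
                                                 mut_prob, rng))
            if len(children) < cfg.population_size:
                children.append(_polynomial_mutation(c2, bounds, cfg.mutation_eta,
                                                     mut_prob, rng))
        child_accs = [fitness(g) for g in children]

        union = pop + children
        union_accs = accs + child_accs
        union_objs = np.stack([objectives(g, a) for g, a in zip(union, union_accs)])
        fronts = _fast_non_dominated_sort(union_objs)
        survivors: list[int] = []
        for front in fronts:
            if len(survivors) + len(front) <= cfg.population_size:
                survivors.extend(front)
            else:
                cd = _crowding(union_objs, front)
                order = np.argsort(-cd)
                need = cfg.population_size - len(survivors)
                survivors.extend([front[k] for k in order[:need]])
                break
        pop = [union[i] for i in survivors]
        accs = [union_accs[i] for i in survivors]
        best_i = int(np.argmax(accs))
        result.history.append({"generation": _gen, "best": float(accs[best_i]),
                               "mean": float(np.mean(accs))})
        if accs[best_i] > result.best_fitness:
            result.best_fitness = float(accs[best_i])
            result.best_genes = pop[best_i].copy()
            result.best_config = decode_genes(pop[best_i], space, base)
    return result
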