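"""Shared test helpers: instance builder + independent ML oracle for the EM.

The oracle maximizes the compatibility-class log-likelihood

    L(d) = sum_c n_c log(sum_{t in c} d_t) - N log(sum_t d_t y_t)

over the direction simplex d directly (bounded 1-d search for two
transcripts, multi-start SLSQP otherwise) — no EM anywhere.  Expected
counts follow as x_t = sum_c n_c d_t / sum_{t' in c} d_{t'}.

For instances with exact symmetries (transcripts indistinguishable by
length and compatibility), only class probabilities are identified; the
oracle is symmetrized by averaging x over the instance's automorphisms.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from annodepth import synthetic_data as sd

__all__ = ["build_instance", "oracle_fit", "OracleFit"]


def build_instance(class_sets, class_counts, lengths):
    """(Annotation, ReadSet) realizing a compatibility-class structure.

    ``class_sets``: tuples of transcript indices; each class is one shared
    block of length 1, plus a private filler block per transcript to reach
    its target length.
    """
    n_tx = len(lengths)
    txs = []
    for k in range(n_tx):
        blocks = [sd.Block(f"c{i}", 1) for i, s in enumerate(class_sets) if k in s]
        fill = lengths[k] - len(blocks)
        if fill < 0:
            raise ValueError(f"length {lengths[k]} too small for transcript {k}")
        if fill > 0:
            blocks.append(sd.Block(f"fill{k}", fill))
        txs.append(sd.Transcript(f"t{k}", f"g{k}", f"fam{k}", tuple(blocks)))
    ann = sd.Annotation("instance", tuple(txs))

    vocab: dict[str, int] = {}
    block_codes: list[int] = []
    origin_codes: list[int] = []
    for i, (s, n) in enumerate(zip(class_sets, class_counts)):
        if n == 0:
            continue
        code = vocab.setdefault(f"c{i}", len(vocab))
        block_codes.extend([code] * n)
        origin_codes.extend([s[0]] * n)
    reads = sd.ReadSet(
        block_vocab=np.array(list(vocab), dtype=object),
        tx_vocab=np.array([f"t{k}" for k in range(n_tx)], dtype=object),
        block_codes=np.array(block_codes, dtype=np.int64),
        origin_codes=np.array(origin_codes, dtype=np.int64),
    )
    return ann, reads


class OracleFit:
    def __init__(self, x, direction, neg_ll_opt, neg_ll):
        self.x = x
        self.direction = direction
        self.neg_ll_opt = neg_ll_opt
        self.neg_ll = neg_ll

    def neg_ll_of_counts(self, x_counts, lengths) -> float:
        """Evaluate the class likelihood at the direction implied by counts x."""
        y = np.asarray(lengths, float)
        d = np.asarray(x_counts, float) / y
        total = d.sum()
        if total <= 0:
            return np.inf
        return self.neg_ll(d / total)


def _neg_ll_factory(class_sets, class_counts, lengths):
    n_tx = len(lengths)
    y = np.asarray(lengths, float)
    n = np.asarray(class_counts, float)
    total_reads = n.sum()
    A = np.zeros((len(class_sets), n_tx))
    for i, s in enumerate(class_sets):
        A[i, list(s)] = 1.0

    def neg_ll(d):
        d = np.maximum(np.asarray(d, float), 0.0)
        cs = A @ d
        if (cs[n > 0] <= 0).any() or (d * y).sum() <= 0:
            return 1e12
        with np.errstate(divide="ignore"):
            logs = np.where(cs > 0, np.log(np.where(cs > 0, cs, 1.0)), 0.0)
        return float(-(n * logs).sum() + total_reads * np.log((d * y).sum()))

    return neg_ll, A, n


def _automorphisms(class_sets, class_counts, lengths):
    n_tx = len(lengths)
    base = {}
    for s, c in zip(class_sets, class_counts):
        key = tuple(sorted(s))
        base[key] = base.get(key, 0) + c
    perms = []
    for p in itertools.permutations(range(n_tx)):
        if any(lengths[p[k]] != lengths[k] for k in range(n_tx)):
            continue
        mapped: dict[tuple, float] = {}
        for s, c in zip(class_sets, class_counts):
            key = tuple(sorted(p[k] for k in s))
            mapped[key] = mapped.get(key, 0) + c
        if mapped == base:
            perms.append(p)
    return perms


def _simplex_grid(n_tx: int, step: float) -> np.ndarray:
    """All points of the probability simplex on a regular grid."""
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    if n_tx == 3:
        a, b = np.meshgrid(ticks, ticks, indexing="ij")
        mask = a + b <= 1.0 + 1e-12
        pts = np.column_stack([a[mask], b[mask], 1.0 - a[mask] - b[mask]])
        return np.maximum(pts, 0.0)
    pts = []
    for combo in np.ndindex(*([len(ticks)] * (n_tx - 1))):
        vals = ticks[list(combo)]
        rest = 1.0 - vals.sum()
        if rest >= -1e-12:
            pts.append(np.append(vals, max(rest, 0.0)))
    return np.array(pts)


def oracle_fit(class_sets, class_counts, lengths, n_random_starts=1) -> OracleFit:
    """Brute-force ML fit; x symmetrized over instance automorphisms."""
    n_tx = len(lengths)
    neg_ll, A, n = _neg_ll_factory(class_sets, class_counts, lengths)

    if n_tx == 2:
        res = minimize_scalar(lambda p: neg_ll(np.array([p, 1.0 - p])),
                              bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-13})
        candidates = [np.array([res.x, 1.0 - res.x]),
                      np.array([1.0, 0.0]), np.array([0.0, 1.0])]
        d = min(candidates, key=neg_ll)
    else:
        cons = ({"type": "eq", "fun": lambda d: d.sum() - 1.0},)
        bounds = [(0.0, 1.0)] * n_tx
        # coarse vectorized grid over the simplex, then SLSQP polish
        y = np.asarray(lengths, float)
        grid = _simplex_grid(n_tx, step=0.025)
        cs = grid @ A.T                       # (P, n_classes)
        lib = grid @ y
        with np.errstate(divide="ignore"):
            logs = np.where(cs > 0, np.log(np.where(cs > 0, cs, 1.0)), -1e6)
        vals = -(logs * n).sum(axis=1) + n.sum() * np.log(lib)
        starts = [grid[int(np.argmin(vals))], np.full(n_tx, 1.0 / n_tx)]
        rng = np.random.default_rng(12345)
        starts.extend(rng.dirichlet(np.ones(n_tx)) for _ in range(n_random_starts))
        d, best = None, np.inf
        for s0 in starts:
            r = minimize(neg_ll, s0, method="SLSQP", bounds=bounds, constraints=cons,
                         options={"ftol": 1e-14, "maxiter": 400})
            cand = np.maximum(r.x, 0.0)
            val = neg_ll(cand)
            if val < best:
                best, d = val, cand

    def counts_of(direction):
        cs = A @ direction
        x = np.zeros(n_tx)
        for i, s in enumerate(class_sets):
            if n[i] == 0 or cs[i] <= 0:
                continue
            idx = list(s)
            x[idx] += n[i] * direction[idx] / cs[i]
        return x

    x = counts_of(d)
    autos = _automorphisms(class_sets, class_counts, lengths)
    if len(autos) > 1:
        acc = np.zeros(n_tx)
        for p in autos:
            inv = np.argsort(p)
            acc += x[inv]
        x = acc / len(autos)
    return OracleFit(x=x, direction=d, neg_ll_opt=neg_ll(d), neg_ll=neg_ll)
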