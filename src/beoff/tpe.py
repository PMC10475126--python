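"""Tree-structured Parzen Estimator (TPE) hyperparameter search.

Sequential model-based optimisation: completed trials are split into a
good fraction (top ``gamma`` by objective) and the rest; each parameter gets
a one-dimensional Parzen (kernel) density l(x) over the good values and g(x)
over the bad ones, candidates are drawn from l, and the candidate maximising
l(x)/g(x) -- the expected-improvement surrogate -- is evaluated next. The
first ``n_startup`` trials are random to seed the densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Float:
    low: float
    high: float
    log: bool = False


@dataclass(frozen=True)
class Int:
    low: int
    high: int
    log: bool = False


@dataclass(frozen=True)
class Choice:
    options: tuple


def _sample_random(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, p in space.items():
        if isinstance(p, Choice):
            out[name] = p.options[rng.integers(len(p.options))]
        elif isinstance(p, (Float, Int)):
            lo, hi = (math.log(p.low), math.log(p.high)) if p.log else (p.low, p.high)
            v = rng.uniform(lo, hi)
            if p.log:
                v = min(max(math.exp(v), p.low), p.high)
            out[name] = int(round(v)) if isinstance(p, Int) else v
        else:
            raise TypeError(f"unknown parameter type for {name!r}")
    return out


def _parzen_logpdf(x: np.ndarray, obs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Log density of a uniform-prior Parzen mixture with Scott-style bandwidth."""
    n = len(obs)
    span = hi - lo
    bw = max(span / max(np.sqrt(n), 1.0), 1e-3 * span, 1e-12)
    comps = np.concatenate([obs, [(lo + hi) / 2.0]])  # uniform-ish prior kernel
    bws = np.full(len(comps), bw)
    bws[-1] = span  # wide prior component
    diff = (x[:, None] - comps[None, :]) / bws[None, :]
    log_k = -0.5 * diff**2 - np.log(bws[None, :] * np.sqrt(2 * np.pi))
    m = log_k.max(axis=1, keepdims=True)
    return (m[:, 0] + np.log(np.exp(log_k - m).sum(axis=1))) - np.log(len(comps))


def suggest(space: dict, trials: list[tuple[dict, float]], rng: np.random.Generator,
            gamma: float = 0.25, n_candidates: int = 24, n_startup: int = 8) -> dict:
    """Propose the next configuration; ``trials`` holds (params, score) with
    higher scores better."""
    if len(trials) < n_startup:
        return _sample_random(space, rng)
    scores = np.array([s for _, s in trials])
    order = np.argsort(-scores)
    n_good = max(1, int(np.ceil(gamma * len(trials))))
    good = [trials[i][0] for i in order[:n_good]]
    bad = [trials[i][0] for i in order[n_good:]] or good
    out = {}
    for name, p in space.items():
        if isinstance(p, Choice):
            counts_g = np.array([sum(1 for t in good if t[name] == o) for o in p.options], float) + 1
            counts_b = np.array([sum(1 for t in bad if t[name] == o) for o in p.options], float) + 1
            ratio = (counts_g / counts_g.sum()) / (counts_b / counts_b.sum())
            draw = rng.choice(len(p.options), size=n_candidates, p=counts_g / counts_g.sum())
            out[name] = p.options[draw[np.argmax(ratio[draw])]]
            continue
        lo, hi = (math.log(p.low), math.log(p.high)) if p.log else (float(p.low), float(p.high))
        tf = (lambda v: math.log(v)) if p.log else (lambda v: float(v))
        obs_g = np.array([tf(t[name]) for t in good])
        obs_b = np.array([tf(t[name]) for t in bad])
        n = len(obs_g)
        span = hi - lo
        bw = max(span / max(np.sqrt(n), 1.0), 1e-3 * span, 1e-12)
        idx = rng.integers(n + 1, size=n_candidates)
        cands = np.where(
            idx < n,
            obs_g[np.minimum(idx, n - 1)] + rng.normal(0, bw, n_candidates),
            rng.uniform(lo, hi, n_candidates),
        )
        cands = np.clip(cands, lo, hi)
        ei = _parzen_logpdf(cands, obs_g, lo, hi) - _parzen_logpdf(cands, obs_b, lo, hi)
        v = cands[np.argmax(ei)]
        if p.log:
            v = min(max(math.exp(v), p.low), p.high)
        out[name] = int(round(v)) if isinstance(p, Int) else float(v)
    return out


def optimize(objective, space: dict, n_trials: int, seed: int = 0,
             gamma: float = 0.25, n_startup: int = 8):
    """Run the search; returns (best_params, best_score, trials)."""
    rng = np.random.default_rng(seed)
    trials: list[tuple[dict, float]] = []
    for _ in range(n_trials):
        params = suggest(space, trials, rng, gamma=gamma, n_startup=n_startup)
        trials.append((params, float(objective(params))))
    best = max(trials, key=lambda t: t[1])
    return best[0], best[1], trials
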