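"""Hand-crafted feature baselines for off:on-target ratio regression.

Features per aligned pair: position-dependent 1-mer indicators over the
{A, C, G, T, -} alphabet for both sequences, position-independent 1-mer
counts, off-target GC content, and the nearest-neighbor RNA/DNA duplex
binding free energy summed over fully matched 2-bp windows. Four
conventional regressors (linear, ridge, multilayer perceptron,
gradient-boosted trees) are tuned with the TPE searcher on a group-aware
validation split and compared head-to-head with the recurrent model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.neural_network import MLPRegressor
from xgboost import XGBRegressor

from . import tpe
from .seqrep import GAP, GuideTargetPair

#: RNA/DNA hybrid nearest-neighbor free energies (kcal/mol, 37 C), keyed by
#: the guide-strand dinucleotide written 5'->3' in DNA letters (T for U).
#: Values follow the Sugimoto 1995 RNA/DNA parameter set; the table is
#: swappable wherever it is consumed.
SUGIMOTO_RNA_DNA = {
    "AA": -1.0, "AC": -2.1, "AG": -1.8, "AT": -0.9,
    "CA": -0.9, "CC": -2.1, "CG": -1.7, "CT": -0.9,
    "GA": -1.3, "GC": -2.7, "GG": -2.9, "GT": -1.1,
    "TA": -0.6, "TC": -1.5, "TG": -1.6, "TT": -0.2,
}


@dataclass(frozen=True)
class EnergyTable:
    values: dict = field(default_factory=lambda: dict(SUGIMOTO_RNA_DNA))
    name: str = "sugimoto-rna-dna-1995"

    def __post_init__(self):
        missing = {a + b for a in "ACGT" for b in "ACGT"} - set(self.values)
        if missing:
            raise ValueError(f"energy table is missing dinucleotides: {sorted(missing)}")

    def __getitem__(self, dinuc: str) -> float:
        try:
            return self.values[dinuc]
        except KeyError:
            raise KeyError(f"dinucleotide {dinuc!r} absent from energy table {self.name}") from None


def nn_free_energy(aligned_guide: str, aligned_off: str,
                   table: EnergyTable = EnergyTable()) -> float:
    """Nearest-neighbor binding free energy over the matched duplex.

    A 2-bp window slides along the alignment; a window contributes its
    dinucleotide energy only when both of its columns are matches (non-gap
    and identical on both strands). Mismatched or gapped windows contribute
    nothing, so a fully mismatched pair scores 0.
    """
    if len(aligned_guide) != len(aligned_off):
        raise ValueError("aligned strings must have equal length")
    match = [
        a == b and a != GAP for a, b in zip(aligned_guide, aligned_off)
    ]
    energy = 0.0
    for i in range(len(match) - 1):
        if match[i] and match[i + 1]:
            energy += table[aligned_guide[i] + aligned_guide[i + 1]]
    return energy


_ALPHABET = "ACGT" + GAP


def feature_names(pad_to: int = 26) -> list[str]:
    names = [
        f"{seq}_pos{p}_{c}"
        for seq in ("guide", "off")
        for p in range(pad_to)
        for c in _ALPHABET
    ]
    names += [f"{seq}_count_{c}" for seq in ("guide", "off") for c in "ACGT"]
    names += ["off_gc_content", "nn_free_energy"]
    return names


def featurize(pair: GuideTargetPair, pad_to: int = 26,
              table: EnergyTable = EnergyTable()) -> np.ndarray:
    """Deterministic fixed-width feature vector for one aligned pair.

    Feature order matches :func:`feature_names` and is stable.
    """
    if pair.length > pad_to:
        raise ValueError(f"alignment length {pair.length} exceeds pad_to={pad_to}")
    blocks = []
    for seq in (pair.aligned_guide, pair.aligned_off):
        onehot = np.zeros((pad_to, len(_ALPHABET)))
        for p, c in enumerate(seq):
            onehot[p, _ALPHABET.index(c)] = 1.0
        blocks.append(onehot.ravel())
    counts = []
    for seq in (pair.aligned_guide, pair.aligned_off):
        counts.extend(seq.count(c) for c in "ACGT")
    off = pair.offtarget_seq
    gc = (off.count("G") + off.count("C")) / len(off)
    energy = nn_free_energy(pair.aligned_guide, pair.aligned_off, table)
    return np.concatenate(blocks + [np.array(counts, float), [gc, energy]])


def featurize_all(pairs: list[GuideTargetPair], pad_to: int = 26,
                  table: EnergyTable = EnergyTable()) -> np.ndarray:
    return np.stack([featurize(p, pad_to, table) for p in pairs])


def export_features(pairs: list[GuideTargetPair], path, pad_to: int = 26,
                    table: EnergyTable = EnergyTable()) -> None:
    """Write the feature matrix as TSV with the documented column names."""
    import pandas as pd

    df = pd.DataFrame(featurize_all(pairs, pad_to, table), columns=feature_names(pad_to))
    df.insert(0, "group_id", [p.group_id for p in pairs])
    df.to_csv(path, sep="\t", index=False)


def export_comparison_report(results: dict, path) -> None:
    """Baseline comparison report: model, chosen parameters, Spearman."""
    import pandas as pd

    rows = [
        {"model": name, "val_spearman": r["val_spearman"],
         "test_spearman": r["test_spearman"], "params": str(r["params"])}
        for name, r in results.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# model fitting

SEARCH_SPACES = {
    "ridge": {"alpha": tpe.Float(1e-3, 1e3, log=True)},
    "mlp": {
        "hidden": tpe.Choice((32, 64, 128)),
        "n_layers": tpe.Choice((1, 2)),
        "alpha": tpe.Float(1e-5, 1e-1, log=True),
        "learning_rate_init": tpe.Float(1e-4, 1e-2, log=True),
    },
    "xgboost": {
        "n_estimators": tpe.Int(100, 500, log=True),
        "max_depth": tpe.Int(3, 8),
        "learning_rate": tpe.Float(0.02, 0.3, log=True),
        "subsample": tpe.Float(0.6, 1.0),
        "colsample_bytree": tpe.Float(0.6, 1.0),
        "reg_lambda": tpe.Float(1e-2, 10.0, log=True),
    },
}


def _build(name: str, params: dict, seed: int):
    if name == "linear":
        return LinearRegression()
    if name == "ridge":
        return Ridge(alpha=params["alpha"], random_state=seed)
    if name == "mlp":
        return MLPRegressor(
            hidden_layer_sizes=(params["hidden"],) * params["n_layers"],
            alpha=params["alpha"],
            learning_rate_init=params["learning_rate_init"],
            max_iter=400,
            early_stopping=True,
            random_state=seed,
        )
    if name == "xgboost":
        return XGBRegressor(
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"],
            learning_rate=params["learning_rate"],
            subsample=params["subsample"],
            colsample_bytree=params["colsample_bytree"],
            reg_lambda=params["reg_lambda"],
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    raise ValueError(f"unknown baseline {name!r}")


def _safe_spearman(a, b) -> float:
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        import warnings

        warnings.warn("Spearman undefined for constant input", stacklevel=2)
        return float("nan")
    return float(spearmanr(a, b).statistic)


def fit_baselines(features: np.ndarray, targets: np.ndarray, groups: np.ndarray,
                  split: tuple[np.ndarray, np.ndarray], search_budget: int = 15,
                  seed: int = 0, models: tuple[str, ...] = ("linear", "ridge", "mlp", "xgboost")):
    """Tune and fit the conventional regressors on a group-disjoint split.

    An inner validation block (one fifth of the training groups) scores TPE
    trials; the winning configuration is refit on the full training side and
    evaluated on the held-out side. Returns per-model dicts with the fitted
    estimator, chosen hyperparameters and Spearman correlations.
    """
    from .deepmodel import check_group_disjoint  # shared split hygiene

    train_idx, test_idx = np.asarray(split[0]), np.asarray(split[1])
    check_group_disjoint(groups, train_idx, test_idx)
    rng = np.random.default_rng(seed)
    train_groups = np.unique(groups[train_idx])
    val_groups = set(rng.choice(train_groups, size=max(1, len(train_groups) // 5), replace=False))
    inner_val = train_idx[[groups[i] in val_groups for i in train_idx]]
    inner_fit = train_idx[[groups[i] not in val_groups for i in train_idx]]

    results = {}
    for name in models:
        space = SEARCH_SPACES.get(name, {})
        if space:
            def objective(params, name=name):
                est = _build(name, params, seed)
                est.fit(features[inner_fit], targets[inner_fit])
                return _safe_spearman(est.predict(features[inner_val]), targets[inner_val])

            best_params, best_val, trials = tpe.optimize(
                objective, space, n_trials=search_budget, seed=seed
            )
        else:
            best_params, best_val, trials = {}, float("nan"), []
        est = _build(name, best_params, seed)
        est.fit(features[train_idx], targets[train_idx])
        test_spearman = _safe_spearman(est.predict(features[test_idx]), targets[test_idx])
        results[name] = {
            "model": est,
            "params": best_params,
            "val_spearman": best_val,
            "test_spearman": test_spearman,
            "n_trials": len(trials),
        }
    return results
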