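"""Brain-age model selection, statsmodels-style.

``BrainAgeModel`` holds the training and validation feature tables, the
feature ordering from the ranking stage and the architecture grid;
``fit()`` trains every (input count x architecture) cell three times with
consecutive seeds, selects the cell with the lowest mean validation rmse,
optionally repeats the whole grid with a randomly ordered feature list
(the null model that quantifies the value of the ranking), and returns a
``BrainAgeResults`` carrying the frozen network, the full selection grid
and a ``summary()`` table.  Validation data should come from a site not
present in training; the test set must only ever meet the frozen results
object — ``BrainAgeResults.predict`` never refits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import (
    BrainAgeNet,
    NetArchitecture,
    default_architectures,
    evaluate,
    train_network,
)
from .ranking import StandardizationStats, standardize

__all__ = ["BrainAgeModel", "BrainAgeResults", "SelectionGrid", "run_selection_grid"]

DEFAULT_N_INPUTS = (5, 10, 15, 20, 25)
N_ITERATIONS = 3


@dataclass
class SelectionGrid:
    """Per-cell train/validation rmse and the selected architecture."""

    table: pd.DataFrame  # columns: ordering, n_inputs, architecture, iteration, seed, train_rmse, validation_rmse
    selected: NetArchitecture
    null_seed: int | None = None

    def mean_validation(self, ordering: str = "ranked") -> pd.DataFrame:
        sub = self.table[self.table["ordering"] == ordering]
        return (
            sub.groupby(["n_inputs", "architecture"])[["train_rmse", "validation_rmse"]]
            .mean()
            .reset_index()
        )


def _grid_cells(n_inputs, architectures, n_features):
    cells = []
    for k in n_inputs:
        if k > n_features:
            continue
        for hidden in architectures:
            cells.append(NetArchitecture(n_inputs=k, hidden_layers=tuple(hidden)))
    return cells


def run_selection_grid(
    X_train: np.ndarray,
    age_train: np.ndarray,
    X_val: np.ndarray,
    age_val: np.ndarray,
    feature_order: list[str],
    n_inputs=DEFAULT_N_INPUTS,
    architectures=None,
    base_seed: int = 0,
    decay: float = 0.01,
    n_iterations: int = N_ITERATIONS,
    ordering_label: str = "ranked",
) -> SelectionGrid:
    """Train the full grid and select by mean validation rmse.

    Columns of ``X_train``/``X_val`` must already follow ``feature_order``
    and be standardized with training statistics.  Each cell is trained
    ``n_iterations`` times with seeds (base, base+1, base+2); ties in mean
    validation rmse break by fewer parameters, then fewer inputs.
    """
    architectures = architectures if architectures is not None else default_architectures()
    cells = _grid_cells(n_inputs, architectures, X_train.shape[1])
    if not cells:
        raise ValueError("empty architecture grid")
    rows = []
    for arch in cells:
        cols = slice(0, arch.n_inputs)
        for it in range(n_iterations):
            seed = base_seed + it
            net = train_network(
                X_train[:, cols], age_train, arch, seed=seed, decay=decay
            )
            val_rmse, _, _ = evaluate(net, X_val[:, cols], age_val)
            rows.append(
                {
                    "ordering": ordering_label,
                    "n_inputs": arch.n_inputs,
                    "architecture": "x".join(map(str, arch.hidden_layers)),
                    "iteration": it,
                    "seed": seed,
                    "train_rmse": net.training_rmse,
                    "validation_rmse": val_rmse,
                }
            )
    table = pd.DataFrame(rows)
    means = (
        table.groupby(["n_inputs", "architecture"])["validation_rmse"].mean().reset_index()
    )
    arch_by_key = {
        (a.n_inputs, "x".join(map(str, a.hidden_layers))): a for a in cells
    }
    means["arch_obj"] = [
        arch_by_key[(r.n_inputs, r.architecture)] for r in means.itertuples()
    ]
    means["n_params"] = [a.n_parameters for a in means["arch_obj"]]
    means = means.sort_values(
        ["validation_rmse", "n_params", "n_inputs"], kind="mergesort"
    )
    selected = means.iloc[0]["arch_obj"]
    return SelectionGrid(table=table, selected=selected)


class BrainAgeModel:
    """Brain-age estimator over ranked graph-metric features.

    Parameters
    ----------
    train_features, validation_features :
        Subjects x metrics DataFrames (unstandardized); standardization
        statistics are fitted on the training table and frozen.
    train_age, validation_age :
        Chronological ages in years.
    feature_order :
        Metric names from most to least important (the ranking stage
        output); grid cells use prefixes of this list.
    """

    def __init__(
        self,
        train_features: pd.DataFrame,
        train_age,
        validation_features: pd.DataFrame,
        validation_age,
        feature_order: list[str],
        n_inputs=DEFAULT_N_INPUTS,
        architectures=None,
        decay: float = 0.01,
    ):
        missing = set(feature_order) - set(train_features.columns)
        if missing:
            raise ValueError(f"feature_order names absent from features: {missing}")
        self.feature_order = list(feature_order)
        self.train_features = train_features[self.feature_order]
        self.validation_features = validation_features[self.feature_order]
        self.train_age = np.asarray(train_age, dtype=float)
        self.validation_age = np.asarray(validation_age, dtype=float)
        self.n_inputs = tuple(n_inputs)
        self.architectures = architectures
        self.decay = decay
        self.standardization = StandardizationStats.fit(self.train_features)

    def _standardized(self, features: pd.DataFrame) -> np.ndarray:
        return standardize(features[self.feature_order],
                           StandardizationStats(
                               tuple(self.feature_order),
                               self.standardization.mean,
                               self.standardization.sd,
                           )).to_numpy()

    def fit(
        self,
        seed: int = 0,
        with_null: bool = False,
        null_seed: int | None = None,
        n_iterations: int = N_ITERATIONS,
    ) -> "BrainAgeResults":
        """Run the selection grid (and optional random-order null)."""
        Xtr = self._standardized(self.train_features)
        Xva = self._standardized(self.validation_features)
        grid = run_selection_grid(
            Xtr,
            self.train_age,
            Xva,
            self.validation_age,
            self.feature_order,
            n_inputs=self.n_inputs,
            architectures=self.architectures,
            base_seed=seed,
            decay=self.decay,
            n_iterations=n_iterations,
        )
        table = grid.table
        if with_null:
            nseed = null_seed if null_seed is not None else seed + 104659
            rng = np.random.default_rng(nseed)
            perm = rng.permutation(len(self.feature_order))
            null_order = [self.feature_order[i] for i in perm]
            null_grid = run_selection_grid(
                Xtr[:, perm],
                self.train_age,
                Xva[:, perm],
                self.validation_age,
                null_order,
                n_inputs=self.n_inputs,
                architectures=self.architectures,
                base_seed=seed,
                decay=self.decay,
                n_iterations=n_iterations,
                ordering_label="random",
            )
            table = pd.concat([table, null_grid.table], ignore_index=True)
            grid = SelectionGrid(table=table, selected=grid.selected, null_seed=nseed)

        # freeze the selected architecture: among its iterations, keep the
        # seed with the lowest validation rmse (deterministic tie-break by
        # iteration order)
        sel = grid.selected
        sub = grid.table[
            (grid.table["ordering"] == "ranked")
            & (grid.table["n_inputs"] == sel.n_inputs)
            & (grid.table["architecture"] == "x".join(map(str, sel.hidden_layers)))
        ].sort_values(["validation_rmse", "iteration"], kind="mergesort")
        best_seed = int(sub.iloc[0]["seed"])
        cols = slice(0, sel.n_inputs)
        net = train_network(
            Xtr[:, cols], self.train_age, sel, seed=best_seed, decay=self.decay
        )
        val_rmse, val_mae, _ = evaluate(net, Xva[:, cols], self.validation_age)
        return BrainAgeResults(
            model=self,
            net=net,
            selection_grid=grid,
            feature_list=self.feature_order[: sel.n_inputs],
            validation_rmse=val_rmse,
            validation_mae=val_mae,
        )


@dataclass
class BrainAgeResults:
    """Frozen selected network plus the evidence that selected it."""

    model: BrainAgeModel
    net: BrainAgeNet
    selection_grid: SelectionGrid
    feature_list: list[str]
    validation_rmse: float
    validation_mae: float

    @property
    def architecture(self) -> NetArchitecture:
        return self.net.architecture

    @property
    def training_rmse(self) -> float:
        return self.net.training_rmse

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Predicted ages for new subjects; the model is never refitted."""
        missing = set(self.feature_list) - set(features.columns)
        if missing:
            raise ValueError(f"missing metric column(s): {missing}")
        full = features.reindex(columns=self.model.feature_order)
        if full.isna().any().any():
            raise ValueError("feature table has missing values")
        X = self.model._standardized(full)
        return self.net.predict(X[:, : self.architecture.n_inputs])

    def summary(self) -> str:
        sel = self.architecture
        lines = [
            "Brain age model selection",
            "=" * 60,
            f"grid cells (ranked ordering): "
            f"{len(self.selection_grid.table[self.selection_grid.table.ordering == 'ranked']) // max(1, self.selection_grid.table['iteration'].max() + 1)}",
            f"selected architecture: {sel.n_inputs} inputs, hidden "
            f"{'x'.join(map(str, sel.hidden_layers))} "
            f"({sel.n_parameters} parameters)",
            f"input metrics: {', '.join(self.feature_list)}",
            f"training rmse: {self.training_rmse:8.3f} years",
            f"validation rmse: {self.validation_rmse:6.3f} years",
            f"validation mae: {self.validation_mae:7.3f} years",
            f"weight decay lambda: {self.net.decay_coefficient}",
            f"training seed: {self.net.training_seed}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        payload = {
            "architecture": {
                "n_inputs": self.architecture.n_inputs,
                "hidden_layers": list(self.architecture.hidden_layers),
            },
            "feature_order": self.model.feature_order,
            "feature_list": self.feature_list,
            "standardization": {
                "feature_names": list(self.model.feature_order),
                "mean": self.model.standardization.mean.tolist(),
                "sd": self.model.standardization.sd.tolist(),
            },
            "weights": [w.tolist() for w in self.net.weights],
            "biases": [b.tolist() for b in self.net.biases],
            "training_seed": self.net.training_seed,
            "decay_coefficient": self.net.decay_coefficient,
            "target_mean": self.net.target_mean,
            "target_sd": self.net.target_sd,
            "training_rmse": self.training_rmse,
            "validation_rmse": self.validation_rmse,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @staticmethod
    def load_frozen(path) -> "FrozenBrainAge":
        return FrozenBrainAge.load(path)


@dataclass
class FrozenBrainAge:
    """A predictor reconstructed from ``model.json`` — weights only."""

    net: BrainAgeNet
    feature_order: list[str]
    feature_list: list[str]
    standardization: StandardizationStats

    @classmethod
    def load(cls, path) -> "FrozenBrainAge":
        payload = json.loads(Path(path).read_text())
        arch = NetArchitecture(
            n_inputs=payload["architecture"]["n_inputs"],
            hidden_layers=tuple(payload["architecture"]["hidden_layers"]),
        )
        net = BrainAgeNet(
            architecture=arch,
            weights=[np.array(w) for w in payload["weights"]],
            biases=[np.array(b) for b in payload["biases"]],
            training_seed=payload["training_seed"],
            decay_coefficient=payload["decay_coefficient"],
            target_mean=payload.get("target_mean", 0.0),
            target_sd=payload.get("target_sd", 1.0),
            training_rmse=payload.get("training_rmse", np.nan),
        )
        stats = StandardizationStats(
            tuple(payload["standardization"]["feature_names"]),
            np.array(payload["standardization"]["mean"]),
            np.array(payload["standardization"]["sd"]),
        )
        return cls(
            net=net,
            feature_order=payload["feature_order"],
            feature_list=payload["feature_list"],
            standardization=stats,
        )

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        full = features.reindex(columns=self.feature_order)
        if full.isna().any().any():
            raise ValueError("feature table has missing values")
        X = standardize(full, self.standardization).to_numpy()
        return self.net.predict(X[:, : self.net.architecture.n_inputs])
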