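"""Architecture grid enumeration, multi-restart training, and ranking.

The search grid crosses four code dimensions {2, 5, 10, 20}, all 16
encoder x decoder activation pairs, and the two families (vanilla, deep),
for 4 x 16 x 2 = 128 architectures.  Regularization is a grid-level toggle,
not a fourth axis: the grid is enumerated either on its plain branch (with
weight tying on by default) or on its orthogonality branch.

Because training converges to different local minima depending on the random
initialization, every architecture is trained ``restarts`` times (default 3)
from distinct seeds derived deterministically from a master seed, and the
mean and population variance of the per-restart test MSEs are reported.  PCA
trained on the same training split serves as the per-code-dim baseline.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autoencoders import (
    ActivationKind,
    AEArchitectureSpec,
    TrainConfig,
    build_model,
    reconstruction_mse,
    train,
)
from .baselines import pca_fit, pca_mse
from .errors import InvalidSpecError
from .superpose import DeviationDataset

__all__ = ["SearchGrid", "SearchRecord", "enumerate_grid", "run_search", "rank_report"]

_ACTIVATIONS = ("identity", "sigmoid", "leaky_relu", "parametric_leaky_relu")


@dataclass(frozen=True)
class SearchGrid:
    """The architecture grid; defaults reproduce the full 128-point search."""

    code_dims: tuple[int, ...] = (2, 5, 10, 20)
    activations: tuple[str, ...] = _ACTIVATIONS
    families: tuple[str, ...] = ("vanilla", "deep")
    regularization: str = "plain"
    tie_plain_branch: bool = True
    restarts: int = 3

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise InvalidSpecError("restarts must be at least 1")
        if not self.code_dims or not self.activations or not self.families:
            raise InvalidSpecError("grid axes must be nonempty")
        if self.regularization not in ("plain", "orthogonality"):
            raise InvalidSpecError(
                f"unknown regularization branch {self.regularization!r}"
            )

    @property
    def size(self) -> int:
        return len(self.code_dims) * len(self.activations) ** 2 * len(self.families)


@dataclass
class SearchRecord:
    """Result of one architecture: per-restart test MSEs and the baseline."""

    spec: AEArchitectureSpec
    restart_mses: list[float] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)
    mean_mse: float = float("nan")
    var_mse: float = float("nan")
    baseline_pca_mse: float = float("nan")
    wall_clock_s: float = 0.0

    def finalize(self) -> None:
        if self.restart_mses:
            arr = np.asarray(self.restart_mses)
            self.mean_mse = float(arr.mean())
            # population variance over the restarts
            self.var_mse = float(arr.var())


def enumerate_grid(grid: SearchGrid) -> list[AEArchitectureSpec]:
    """All architecture specs of the grid, in deterministic order.

    Ordering: code_dim, family, encoder activation, decoder activation.
    No duplicates.
    """
    orth = grid.regularization == "orthogonality"
    specs = []
    for code_dim in grid.code_dims:
        for family in grid.families:
            for enc in grid.activations:
                for dec in grid.activations:
                    specs.append(
                        AEArchitectureSpec(
                            family=family,
                            code_dim=code_dim,
                            encoder_activation=ActivationKind(enc),
                            decoder_activation=ActivationKind(dec),
                            tie_weights=grid.tie_plain_branch and not orth,
                            orthogonality=orth,
                        )
                    )
    return specs


def _restart_seed(master_seed: int, spec_index: int, restart: int) -> int:
    ss = np.random.SeedSequence([master_seed, spec_index, restart])
    return int(ss.generate_state(1)[0] % 2**31)


def run_search(
    grid: SearchGrid,
    dataset: DeviationDataset,
    config: TrainConfig | None = None,
    master_seed: int = 0,
) -> list[SearchRecord]:
    """Train every grid point ``restarts`` times and record test MSEs.

    Restart seeds derive deterministically from ``master_seed`` and the
    spec's position, so the whole search is reproducible.  A restart whose
    training diverges is recorded in the record's ``failures`` rather than
    aborting the search.  The PCA baseline is fit once per code dimension on
    the same training split and scored on the same test split.
    """
    config = config or TrainConfig()
    for part in ("train", "validation", "test"):
        if part not in dataset.split:
            raise InvalidSpecError(f"dataset is missing the {part!r} split")
    X_train = dataset.rows("train")
    X_test = dataset.rows("test")

    pca_baselines = {}
    for code_dim in sorted({s.code_dim for s in enumerate_grid(grid)}):
        model = pca_fit(X_train, code_dim)
        pca_baselines[code_dim] = pca_mse(model, X_test)

    records = []
    for idx, spec in enumerate(enumerate_grid(grid)):
        record = SearchRecord(spec=spec, baseline_pca_mse=pca_baselines[spec.code_dim])
        t0 = time.perf_counter()
        for restart in range(grid.restarts):
            seed = _restart_seed(master_seed, idx, restart)
            model = build_model(spec, dataset.input_dim, seed=seed)
            run_config = TrainConfig(
                epochs=config.epochs,
                batch_size=config.batch_size,
                learning_rate=config.learning_rate,
                leaky_alpha=config.leaky_alpha,
                seed=seed,
                orthogonality_beta=config.orthogonality_beta,
            )
            try:
                train(model, dataset, run_config)
                mse, _ = reconstruction_mse(model, X_test)
                record.restart_mses.append(mse)
            except Exception as exc:  # training failure is data, not fatal
                record.failures.append(f"restart {restart}: {exc}")
        record.wall_clock_s = time.perf_counter() - t0
        record.finalize()
        records.append(record)
    return records


def rank_report(records: list[SearchRecord]) -> pd.DataFrame:
    """Records as a table sorted by mean test MSE (ascending).

    Ties break by variance, then by original spec order; the best record of
    each family is flagged.
    """
    if not records:
        raise InvalidSpecError("no records to rank")
    rows = []
    for order, rec in enumerate(records):
        spec = rec.spec
        rows.append(
            dict(
                name=spec.name(),
                family=spec.family,
                code_dim=spec.code_dim,
                encoder_activation=spec.encoder_activation.kind,
                decoder_activation=spec.decoder_activation.kind,
                tie_weights=spec.tie_weights,
                orthogonality=spec.orthogonality,
                mean_mse=rec.mean_mse,
                var_mse=rec.var_mse,
                restart_mses=";".join(f"{v:.6g}" for v in rec.restart_mses),
                n_failures=len(rec.failures),
                baseline_pca_mse=rec.baseline_pca_mse,
                wall_clock_s=rec.wall_clock_s,
                _order=order,
            )
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["mean_mse", "var_mse", "_order"], kind="stable", na_position="last"
    ).reset_index(drop=True)
    best_flags = np.zeros(len(df), dtype=bool)
    for family in df["family"].unique():
        best_flags[df.index[df["family"] == family][0]] = True
    df["family_best"] = best_flags
    return df.drop(columns="_order")
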