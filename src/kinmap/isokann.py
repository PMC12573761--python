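"""Learning the membership function chi by the ISOKANN fixed-point iteration.

The membership function chi: Gamma -> [0, 1] is the affine rescaling of
the leading nontrivial Koopman eigenfunction; chi(x) reads as the degree
of membership of state x in one of the two dominant metastable
macro-states.  ISOKANN finds it without ever assembling a Koopman
matrix: starting from an arbitrary scalar function f_0, it alternates

1. a Monte-Carlo application of the Koopman operator,
   (K f)(x0_n) ~= mean_m f(xtau_{n,m}),  estimated from M burst
   endpoints per initial state,
2. a shift-scale normalization S(v) = (v - min v) / (max v - min v),
   which pins the iterate away from the trivial constant eigenfunction
   and keeps targets inside [0, 1],
3. a regression step fitting a scalar model to the normalized targets,
   giving a function that can again be evaluated at burst endpoints.

The composite update f_{k+1} = S K f_k is a power iteration on the
non-trivial part of the spectrum, so f_k converges to chi.

Two regressors ship with the package: a feedforward network (the choice
for high-dimensional molecular features) and a radial-basis interpolant
(preferable at d <= 3, where it converges in very few iterations).  Any
object honoring the small fit/predict contract can be substituted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol

import numpy as np

from .toy_dynamics import EnsembleData

__all__ = [
    "DegenerateSpectrumError",
    "IsokannConfig",
    "ChiModel",
    "ConvergenceReport",
    "NeuralRegressor",
    "RBFRegressor",
    "shift_scale",
    "koopman_estimate",
    "isokann_fit",
    "orient_chi",
]

logger = logging.getLogger(__name__)


class DegenerateSpectrumError(ValueError):
    """Constant Koopman image: the iterate collapsed onto the trivial
    eigenfunction.  Typically remedied by a longer lag or more states."""


class Regressor(Protocol):
    def fit(self, inputs: np.ndarray, targets: np.ndarray, *, epochs: int,
            batch_size: int, learning_rate: float, seed: int) -> "Regressor": ...

    def predict(self, inputs: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class IsokannConfig:
    """Hyperparameters of the fixed-point iteration.

    ``epochs_per_iteration`` gradient-descent epochs are run at each
    ISOKANN step on the *same* regressor (warm start), so the total
    training effort grows with the iteration count.  ``convergence_tol``
    bounds the max absolute change of chi on X0 between iterations.
    """

    max_iterations: int = 100
    epochs_per_iteration: int = 15
    batch_size: int = 100
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    validation_fraction: float = 0.2
    convergence_tol: float = 1e-3
    seed: int = 0
    overfit_gap_factor: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in (0, 1)")
        for name in ("max_iterations", "epochs_per_iteration", "batch_size",
                     "learning_rate", "convergence_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")


@dataclass
class ConvergenceReport:
    train_loss: list = field(default_factory=list)
    validation_loss: list = field(default_factory=list)
    chi_change: list = field(default_factory=list)
    converged: bool = False
    iterations_run: int = 0
    overfit_warned: bool = False


@dataclass
class ChiModel:
    """A trained chi approximator.

    ``predict`` returns values clamped to [0, 1] (clamping happens only
    at read-out; training targets are already bounded by the
    shift-scale).  ``orientation_flipped`` records whether the model
    reports 1 - f(x) to satisfy an orientation convention — chi and
    1 - chi are equally valid fixed points of the iteration.
    """

    regressor: Regressor
    feature_transform: Optional[Callable[[np.ndarray], np.ndarray]] = None
    feature_kind: str = "cartesian"
    orientation_flipped: bool = False
    max_overshoot: float = 0.0

    def _featurize(self, states: np.ndarray) -> np.ndarray:
        return states if self.feature_transform is None else self.feature_transform(states)

    def predict_raw(self, states: np.ndarray) -> np.ndarray:
        vals = np.asarray(self.regressor.predict(self._featurize(states)), dtype=float)
        return 1.0 - vals if self.orientation_flipped else vals

    def predict(self, states: np.ndarray) -> np.ndarray:
        raw = self.predict_raw(states)
        overshoot = float(max(np.max(raw, initial=0.0) - 1.0, -np.min(raw, initial=0.0), 0.0))
        if overshoot > self.max_overshoot:
            self.max_overshoot = overshoot
            if overshoot > 0.05:
                logger.info("chi overshoot beyond [0,1] by %.3g before clamping", overshoot)
        return np.clip(raw, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Regressors
# ---------------------------------------------------------------------------


class NeuralRegressor:
    """Feedforward network regressor with warm-started minibatch training.

    Architecture defaults scale with input dimension: a single hidden
    layer of 128 sigmoid units for low-dimensional inputs (d < 32), a
    two-layer rectifier pyramid (F/2, F/4) for high-dimensional feature
    vectors.  Parameters persist across ``fit`` calls so each ISOKANN
    iteration continues training where the previous one stopped.

    Plain minibatch SGD is the default solver: its implicit smoothing
    keeps the learned surface gently varying between sparsely sampled
    basins, which stabilizes the fixed point of the outer iteration;
    adaptive solvers sharpen chi faster but pin small basins to
    arbitrary extremes run-to-run.
    """

    def __init__(self, hidden_layer_sizes=None, activation=None,
                 weight_decay: float = 0.0, solver: str = "sgd"):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.weight_decay = weight_decay
        self.solver = solver
        self._mlp = None

    def _build(self, n_features: int, batch_size: int, learning_rate: float, seed: int):
        from sklearn.neural_network import MLPRegressor

        hidden = self.hidden_layer_sizes
        activation = self.activation
        if hidden is None:
            hidden = (128,) if n_features < 32 else (n_features // 2, n_features // 4)
        if activation is None:
            activation = "logistic" if n_features < 32 else "relu"
        self._mlp = MLPRegressor(
            hidden_layer_sizes=hidden,
            activation=activation,
            solver=self.solver,
            alpha=self.weight_decay,
            batch_size=batch_size,
            learning_rate_init=learning_rate,
            max_iter=1,
            warm_start=True,
            shuffle=True,
            random_state=seed,
            tol=0.0,
            n_iter_no_change=10**9,
        )

    def fit(self, inputs, targets, *, epochs, batch_size, learning_rate, seed):
        inputs = np.asarray(inputs, dtype=float)
        targets = np.asarray(targets, dtype=float)
        if self._mlp is None:
            self._build(inputs.shape[1], batch_size, learning_rate, seed)
        self._mlp.set_params(max_iter=int(epochs))
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", category=ConvergenceWarning)
            self._mlp.fit(inputs, targets)
        return self

    def predict(self, inputs):
        if self._mlp is None:
            raise RuntimeError("regressor has not been fitted")
        return self._mlp.predict(np.asarray(inputs, dtype=float))


class RBFRegressor:
    """Thin-plate-spline radial-basis interpolant (for d <= 3 inputs).

    Interpolants carry no trainable state between iterations: each
    ``fit`` call rebuilds the surface through the current targets, which
    is exactly the regression-free limit of the iteration.  ``epochs``,
    ``learning_rate`` and ``seed`` are accepted for contract
    compatibility and ignored.
    """

    def __init__(self, smoothing: float = 0.0, neighbors: Optional[int] = None,
                 kernel: str = "thin_plate_spline"):
        self.smoothing = smoothing
        self.neighbors = neighbors
        self.kernel = kernel
        self._interp = None

    def fit(self, inputs, targets, *, epochs=0, batch_size=0, learning_rate=0.0, seed=0):
        from scipy.interpolate import RBFInterpolator

        inputs = np.asarray(inputs, dtype=float)
        if inputs.shape[1] > 3:
            raise ValueError("RBFRegressor is intended for inputs with d <= 3")
        self._interp = RBFInterpolator(
            inputs, np.asarray(targets, dtype=float),
            smoothing=self.smoothing, neighbors=self.neighbors, kernel=self.kernel,
        )
        return self

    def predict(self, inputs):
        if self._interp is None:
            raise RuntimeError("regressor has not been fitted")
        return self._interp(np.asarray(inputs, dtype=float))


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def shift_scale(values: np.ndarray) -> np.ndarray:
    """Affine map of a vector onto exactly [0, 1].

    Raises :class:`DegenerateSpectrumError` on (numerically) constant
    input, which in the ISOKANN loop signals collapse onto the trivial
    constant eigenfunction.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("shift_scale expects a vector of at least two values")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise DegenerateSpectrumError(
            "constant Koopman image: cannot rescale a zero-range vector; "
            "increase the lag time or the number of states"
        )
    return (values - lo) / (hi - lo)


def koopman_estimate(fn: Callable[[np.ndarray], np.ndarray],
                     ensemble: EnsembleData) -> np.ndarray:
    """Monte-Carlo estimate of (K_tau fn)(x) at every initial state.

    ``fn`` must map a ``(K, d)`` batch of states to ``K`` scalars; the
    estimate at state n is the average of fn over that state's M burst
    endpoints.
    """
    n, m, d = ensemble.Xtau.shape
    vals = np.asarray(fn(ensemble.Xtau.reshape(n * m, d)), dtype=float)
    if vals.shape != (n * m,):
        raise ValueError("fn must return one scalar per endpoint")
    if not np.all(np.isfinite(vals)):
        bad = int(np.argwhere(~np.isfinite(vals))[0, 0] // m)
        raise FloatingPointError(
            f"non-finite value propagating endpoint of state {bad}"
        )
    return vals.reshape(n, m).mean(axis=1)


def isokann_fit(
    ensemble: EnsembleData,
    regressor: Regressor,
    config: IsokannConfig,
    feature_transform: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    feature_kind: str = "cartesian",
) -> tuple[ChiModel, ConvergenceReport]:
    """Run the ISOKANN iteration to convergence.

    The initial function f_0 is the shift-scaled first feature
    coordinate (any non-constant function works; the iteration washes
    its choice out).  Each iteration estimates the Koopman image of the
    current model on the burst endpoints, rescales it to [0, 1], and
    warm-start-trains the regressor on the result.  Iteration stops when
    max |chi_{k+1}(X0) - chi_k(X0)| < ``convergence_tol`` or after
    ``max_iterations``; non-convergence is flagged in the report, not
    raised.
    """
    transform = feature_transform if feature_transform is not None else (lambda x: x)
    X0f = np.asarray(transform(ensemble.X0), dtype=float)
    n, m, d = ensemble.Xtau.shape
    Xtauf = np.asarray(transform(ensemble.Xtau.reshape(n * m, d)), dtype=float)

    rng = np.random.default_rng(config.seed)
    val_mask = np.zeros(n, dtype=bool)
    val_mask[rng.choice(n, size=max(1, int(round(config.validation_fraction * n))),
                        replace=False)] = True

    model = ChiModel(regressor=regressor, feature_transform=transform,
                     feature_kind=feature_kind)
    report = ConvergenceReport()

    # f_0: shift-scaled first feature coordinate, evaluated on endpoints
    koop = shift_scale(Xtauf[:, 0]).reshape(n, m).mean(axis=1)
    chi_prev = None
    for iteration in range(config.max_iterations):
        targets = shift_scale(koop)
        regressor.fit(
            X0f[~val_mask], targets[~val_mask],
            epochs=config.epochs_per_iteration,
            batch_size=min(config.batch_size, int((~val_mask).sum())),
            learning_rate=config.learning_rate,
            seed=config.seed,
        )
        pred = np.asarray(regressor.predict(X0f), dtype=float)
        train_loss = float(np.mean((pred[~val_mask] - targets[~val_mask]) ** 2))
        val_loss = float(np.mean((pred[val_mask] - targets[val_mask]) ** 2))
        report.train_loss.append(train_loss)
        report.validation_loss.append(val_loss)
        if (not report.overfit_warned and val_loss > 1e-4
                and val_loss > config.overfit_gap_factor * max(train_loss, 1e-12)):
            warnings.warn(
                "validation loss diverging from training loss: possible overfitting",
                stacklevel=2,
            )
            report.overfit_warned = True

        chi_now = np.clip(pred, 0.0, 1.0)
        if chi_prev is not None:
            change = float(np.max(np.abs(chi_now - chi_prev)))
            report.chi_change.append(change)
            if change < config.convergence_tol:
                report.converged = True
                report.iterations_run = iteration + 1
                break
        chi_prev = chi_now
        # Koopman image of the current model for the next targets
        koop = np.asarray(regressor.predict(Xtauf), dtype=float).reshape(n, m).mean(axis=1)
    else:
        report.iterations_run = config.max_iterations
        logger.warning("ISOKANN did not reach tol=%.2g in %d iterations "
                       "(last change %.3g)", config.convergence_tol,
                       config.max_iterations,
                       report.chi_change[-1] if report.chi_change else float("nan"))
    if report.converged:
        logger.info("ISOKANN converged in %d iterations", report.iterations_run)
    return model, report


def orient_chi(
    model: ChiModel,
    ensemble: EnsembleData,
    energies: Optional[np.ndarray] = None,
    rule: str = "energy-min",
) -> ChiModel:
    """Fix the chi vs 1-chi gauge deterministically.

    Default rule: the X0 state with minimum potential energy (when
    ``energies`` are supplied) must have chi < 0.5, i.e. the deepest
    sampled basin is the chi~0 macro-state.  With ``rule='none'`` or
    without energies the trained orientation is kept and recorded.
    Applying the rule twice is a no-op.
    """
    if rule == "none" or energies is None:
        return model
    if rule != "energy-min":
        raise ValueError(f"unknown orientation rule {rule!r}")
    energies = np.asarray(energies, dtype=float)
    ref = int(np.argmin(energies))
    chi_ref = float(model.predict(ensemble.X0[ref : ref + 1])[0])
    if chi_ref > 0.5:
        model.orientation_flipped = not model.orientation_flipped
    return model
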