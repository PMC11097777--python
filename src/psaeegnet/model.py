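"""Model / Results front door, in the spirit of statsmodels.

``PSAEEGNet`` is constructed from data (an EpochSet or raw arrays) plus
configuration; ``fit()`` trains the network and returns a
``PSAEEGNetResults`` carrying the trained parameters, training history,
diagnostics and a ``summary()`` table, with ``predict_proba`` / ``evaluate``
for scoring new epochs.
"""

from __future__ import annotations

import numpy as np

from . import io as _io
from .metrics import MetricsReport, ScoredPredictions, evaluate
from .network import Network, NetworkConfig, build, stage_shapes
from .preprocessing import EpochSet
from .training import TrainConfig, TrainingHistory, fit


class PSAEEGNet:
    """Pyramid-squeeze-attention EEG classifier bound to a training set."""

    def __init__(self, epochs: EpochSet, config: NetworkConfig | None = None,
                 train_config: TrainConfig | None = None):
        if not isinstance(epochs, EpochSet):
            raise TypeError("epochs must be an EpochSet; see from_arrays()")
        self.epochs = epochs
        self.config = config or NetworkConfig(
            n_channels=epochs.n_channels, n_samples=epochs.n_samples)
        self.config.validate()
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_arrays(cls, epochs: np.ndarray, labels: np.ndarray,
                    sampling_rate: float = 250.0, **kwargs) -> "PSAEEGNet":
        return cls(EpochSet(np.asarray(epochs), np.asarray(labels),
                            sampling_rate), **kwargs)

    def fit(self, seed: int | None = None, verbose: bool = False,
            **train_overrides) -> "PSAEEGNetResults":
        tc_kwargs = {**self.train_config.__dict__, **train_overrides}
        if seed is not None:
            tc_kwargs["seed"] = seed
        tc = TrainConfig(**tc_kwargs)
        net = build(self.config, seed=tc.seed)
        net, history = fit(net, self.epochs, tc, verbose=verbose)
        return PSAEEGNetResults(self, net, history, tc)

    def stage_shapes(self):
        return stage_shapes(self.config)


class PSAEEGNetResults:
    """A fitted classifier: parameters, history, scoring and summary."""

    def __init__(self, model: PSAEEGNet, network: Network,
                 history: TrainingHistory, train_config: TrainConfig):
        self.model = model
        self.network = network
        self.history = history
        self.train_config = train_config

    @property
    def params(self) -> dict[str, np.ndarray]:
        return self.network.named_params()

    def predict_proba(self, epochs) -> np.ndarray:
        return self.network.predict_proba(epochs)

    def predict(self, epochs, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(epochs)[:, 1] > threshold).astype(int)

    def evaluate(self, epochs: EpochSet, tie_policy: str = "half") -> MetricsReport:
        probs = self.predict_proba(epochs)
        return evaluate(ScoredPredictions(probs[:, 1], epochs.labels),
                        tie_policy=tie_policy)

    def save(self, path) -> None:
        _io.save_checkpoint(path, self.network)

    def summary(self) -> str:
        ep = self.model.epochs
        n_pos = int((ep.labels == 1).sum())
        c = self.model.config
        lines = [
            "PSAEEGNet results",
            "=" * 48,
            f"{'trials':<28}{len(ep)}",
            f"{'targets / non-targets':<28}{n_pos} / {len(ep) - n_pos}",
            f"{'input (channels x samples)':<28}{ep.n_channels} x {ep.n_samples}",
            f"{'trainable parameters':<28}{self.network.parameter_count()}",
            f"{'PSA (spatial stage)':<28}"
            f"{tuple(c.psa_psfe.kernel_sizes) if c.psa_psfe else 'disabled'}",
            f"{'PSA (deep temporal stage)':<28}"
            f"{tuple(c.psa_dtfe.kernel_sizes) if c.psa_dtfe else 'disabled'}",
            f"{'epochs run':<28}{self.history.n_epochs}",
            f"{'best epoch (restored)':<28}{self.history.best_epoch}",
            f"{'best validation loss':<28}{self.history.best_val_loss:.6f}",
            f"{'final learning rate':<28}{self.history.learning_rate[-1]:.2e}",
            f"{'stopped early':<28}{self.history.stopped_early}",
        ]
        return "\n".join(lines)
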