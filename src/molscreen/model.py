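"""Per-target binding-likelihood model: configuration, splitting, fitting,
prediction, and persistence.

The modelling surface follows the model/results idiom: an
:class:`AffinityModel` is constructed from a labeled dataset and a
:class:`ModelConfig`; its :meth:`~AffinityModel.fit` runs the training loop
and returns an :class:`AffinityResults` carrying the fitted weights, the
per-epoch loss history, and prediction/persistence methods.

Training regime: minibatch Adam, mean-squared error between the
sigmoid-bounded score and the {0,1} activity label, 100 epochs, learning
rate 0.001, batch size 128 by default, with the parameters from the epoch
of lowest validation loss retained (configurable to last-epoch).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import (
    ATOM_FDIM,
    BOND_FDIM,
    FEATURE_SPEC,
    GraphFeatures,
    featurize_smiles,
    pack,
)
from .nn import Adam, MPNNParams, MPNNRegressor
from .records import InvalidSmilesError, LabeledDataset, MoleculeRecord


class SplitError(ValueError):
    """A stratified split left some partition without one of the classes."""


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss); carries the epoch index."""

    def __init__(self, epoch: int, message: str):
        self.epoch = epoch
        super().__init__(f"epoch {epoch}: {message}")


class IncompatibleModelError(RuntimeError):
    """A persisted model does not match the current featurization vocabulary."""


@dataclass
class ModelConfig:
    """Hyperparameters of the per-target predictor.

    Defaults are the reference training regime: a feed-forward head of
    1024/1024/512 hidden nodes, 100 epochs, learning rate 0.001, batch size
    128, MSE loss; message passing depth 3 with 64-dimensional messages.
    """

    hidden_layers: tuple[int, ...] = (1024, 1024, 512)
    epochs: int = 100
    learning_rate: float = 0.001
    batch_size: int = 128
    mp_depth: int = 3
    mp_hidden: int = 64
    seed: int = 0
    model_selection: str = "best_valid"  # or "last"

    def __post_init__(self):
        self.hidden_layers = tuple(int(w) for w in self.hidden_layers)
        if any(w <= 0 for w in self.hidden_layers):
            raise ValueError("hidden layer widths must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.model_selection not in ("best_valid", "last"):
            raise ValueError(f"unknown model_selection {self.model_selection!r}")


@dataclass
class SplitConfig:
    """Train/validation/test fractions (default 70/10/20), seed, stratification."""

    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be >= 0")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {self.fractions}")


def _split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Floor the valid/test fractions; the remainder goes to train."""
    n_valid = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    return n - n_valid - n_test, n_valid, n_test


def split_dataset(
    dataset: LabeledDataset, cfg: SplitConfig
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Partition a dataset into train/valid/test.

    Sizes are the floored fractions of n with the remainder assigned to
    train (400 -> 280/40/80; 302 -> 212/30/60).  When stratified, the rule
    is applied within each class, which preserves those totals and keeps
    class ratios near-constant across partitions.  Deterministic per seed.
    """
    n = len(dataset)
    if n < 10:
        raise ValueError(f"dataset too small to split: {n} < 10")
    rng = np.random.default_rng(cfg.seed)
    if cfg.stratified:
        labels = np.asarray(dataset.labels)
        parts: list[list[int]] = [[], [], []]
        for cls in sorted(set(labels.tolist())):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            n_tr, n_va, n_te = _split_sizes(len(idx), cfg.fractions)
            if min(n_tr, n_va, n_te) == 0 and min(cfg.fractions) > 0:
                raise SplitError(
                    f"class {cls} has {len(idx)} items: a partition would receive 0"
                )
            parts[0] += idx[:n_tr].tolist()
            parts[1] += idx[n_tr:n_tr + n_va].tolist()
            parts[2] += idx[n_tr + n_va:].tolist()
        train_i, valid_i, test_i = (sorted(p) for p in parts)
    else:
        idx = rng.permutation(n)
        n_tr, n_va, _ = _split_sizes(n, cfg.fractions)
        train_i = sorted(idx[:n_tr].tolist())
        valid_i = sorted(idx[n_tr:n_tr + n_va].tolist())
        test_i = sorted(idx[n_tr + n_va:].tolist())
    return dataset.subset(train_i), dataset.subset(valid_i), dataset.subset(test_i)


class AffinityModel:
    """Binding-likelihood model for one protein target.

    Parameters
    ----------
    train : LabeledDataset
        Training molecules with binary activity labels; both classes must
        be present.
    valid : LabeledDataset, optional
        Held-out molecules scored once per epoch; used for best-epoch
        selection when ``config.model_selection == "best_valid"``.
    config : ModelConfig

    Examples
    --------
    >>> model = AffinityModel(train, valid, ModelConfig(epochs=30, seed=0))
    >>> results = model.fit()
    >>> scores = results.predict(test.records)
    """

    def __init__(
        self,
        train: LabeledDataset,
        valid: LabeledDataset | None = None,
        config: ModelConfig | None = None,
    ):
        if len(train) == 0:
            raise ValueError("training set is empty")
        n_act, n_inact = train.class_counts()
        if n_act == 0 or n_inact == 0:
            raise ValueError(
                f"training set for {train.target!r} has a single class "
                f"({n_act} active / {n_inact} inactive)"
            )
        self.train = train
        self.valid = valid
        self.config = config or ModelConfig()
        self.target = train.target

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, target: str, config: ModelConfig | None = None, **kw
    ) -> "AffinityModel":
        """Build from a DataFrame with ``id``, ``smiles`` and ``label`` columns."""
        records = [
            MoleculeRecord(id=str(r.id), smiles=r.smiles, label=int(r.label))
            for r in df.itertuples(index=False)
        ]
        return cls(LabeledDataset(records=records, target=target), config=config, **kw)

    def fit(self, verbose: bool = False) -> "AffinityResults":
        """Run the training loop and return the fitted results object."""
        cfg = self.config
        seeds = np.random.SeedSequence(cfg.seed).spawn(2)
        init_seed = int(seeds[0].generate_state(1)[0] % (2**31))
        shuffle_rng = np.random.default_rng(seeds[1])

        feats = [featurize_smiles(s) for s in self.train.smiles]
        y = np.asarray(self.train.labels, dtype=float)
        valid_batch = valid_y = None
        if self.valid is not None and len(self.valid) > 0:
            valid_batch = pack([featurize_smiles(s) for s in self.valid.smiles])
            valid_y = np.asarray(self.valid.labels, dtype=float)

        net = MPNNRegressor(
            ATOM_FDIM, BOND_FDIM, mp_depth=cfg.mp_depth, mp_hidden=cfg.mp_hidden,
            head_widths=cfg.hidden_layers, seed=init_seed,
        )
        opt = Adam(net.params, lr=cfg.learning_rate)

        n = len(feats)
        history = []
        best_loss, best_params, best_epoch = np.inf, None, -1
        for epoch in range(cfg.epochs):
            order = shuffle_rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                take = order[start:start + cfg.batch_size]
                batch = pack([feats[i] for i in take])
                loss, grads = net.loss_and_grads(batch, y[take])
                if not np.isfinite(loss):
                    raise TrainingError(epoch, f"non-finite training loss {loss}")
                opt.step(grads)
                epoch_loss += loss * len(take)
            epoch_loss /= n

            valid_loss = np.nan
            if valid_batch is not None:
                vs = net.predict(valid_batch)
                valid_loss = float(np.mean((vs - valid_y) ** 2))
                if not np.isfinite(valid_loss):
                    raise TrainingError(epoch, f"non-finite validation loss {valid_loss}")
                if valid_loss < best_loss:
                    best_loss, best_epoch = valid_loss, epoch
                    best_params = net.params.copy()
            history.append((epoch, epoch_loss, valid_loss))
            if verbose:
                print(f"[{self.target}] epoch {epoch:3d} train={epoch_loss:.5f} "
                      f"valid={valid_loss:.5f}")

        if cfg.model_selection == "best_valid" and best_params is not None:
            net.params = best_params
        else:
            best_epoch = cfg.epochs - 1
        hist = pd.DataFrame(history, columns=["epoch", "train_loss", "valid_loss"])
        return AffinityResults(
            target=self.target,
            params=net.params,
            config=cfg,
            training_history=hist,
            feature_spec=FEATURE_SPEC,
            best_epoch=best_epoch,
            seeds={"config": cfg.seed, "init": init_seed},
        )


@dataclass
class AffinityResults:
    """Fitted per-target model: weights, config, loss history, and scoring.

    Scores are guaranteed to lie in [0, 1] by the output sigmoid.
    """

    target: str
    params: MPNNParams
    config: ModelConfig
    training_history: pd.DataFrame
    feature_spec: str
    best_epoch: int
    seeds: dict = field(default_factory=dict)

    def _network(self) -> MPNNRegressor:
        net = MPNNRegressor(
            ATOM_FDIM, BOND_FDIM, mp_depth=self.config.mp_depth,
            mp_hidden=self.config.mp_hidden, head_widths=self.config.hidden_layers,
            seed=0,
        )
        net.params = self.params
        return net

    def predict(self, molecules) -> np.ndarray:
        """Score molecules; one value in [0,1] per input, order preserved.

        Accepts :class:`MoleculeRecord` objects, SMILES strings, or a
        :class:`LabeledDataset`.  Unparseable SMILES are scored ``nan``
        (reported via :meth:`predict_with_report`), never reordered.
        """
        scores, _ = self.predict_with_report(molecules)
        return scores

    def predict_with_report(self, molecules) -> tuple[np.ndarray, list[tuple[int, str]]]:
        """As :meth:`predict`, also returning (position, smiles) of rejects."""
        if self.feature_spec != FEATURE_SPEC:
            raise IncompatibleModelError(
                f"model featurized under {self.feature_spec!r}, "
                f"current vocabulary is {FEATURE_SPEC!r}"
            )
        smiles = [m.smiles if isinstance(m, MoleculeRecord) else m for m in molecules]
        feats: list[GraphFeatures | None] = []
        rejects: list[tuple[int, str]] = []
        for i, s in enumerate(smiles):
            try:
                feats.append(featurize_smiles(s))
            except InvalidSmilesError:
                feats.append(None)
                rejects.append((i, s))
        ok = [f for f in feats if f is not None]
        scores = np.full(len(smiles), np.nan)
        if ok:
            vals = self._network().predict(pack(ok))
            scores[[i for i, f in enumerate(feats) if f is not None]] = vals
        return scores, rejects

    def summary(self) -> str:
        """Human-readable fit summary."""
        h = self.training_history
        lines = [
            f"Binding-likelihood model — target {self.target}",
            "=" * 48,
            f"head widths:        {self.config.hidden_layers}",
            f"message passing:    depth {self.config.mp_depth}, dim {self.config.mp_hidden}",
            f"epochs:             {len(h)} (lr={self.config.learning_rate}, "
            f"batch={self.config.batch_size}, loss=MSE)",
            f"selected epoch:     {self.best_epoch} ({self.config.model_selection})",
            f"final train loss:   {h.train_loss.iloc[-1]:.5f}",
        ]
        if np.isfinite(h.valid_loss.iloc[-1]):
            lines.append(f"best valid loss:    {h.valid_loss.min():.5f}")
        lines.append(f"seeds:              {self.seeds}")
        return "\n".join(lines)

    # ----- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist as a single zip archive (weights .npz + JSON metadata)."""
        buf = io.BytesIO()
        np.savez(buf, **self.params.arrays)
        meta = {
            "format": "molscreen-model-1",
            "target": self.target,
            "config": asdict(self.config),
            "feature_spec": self.feature_spec,
            "best_epoch": self.best_epoch,
            "seeds": self.seeds,
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("weights.npz", buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta, indent=1))
            zf.writestr("history.csv", self.training_history.to_csv(index=False))

    @classmethod
    def load(cls, path: str | Path) -> "AffinityResults":
        """Load a persisted model; refuses mismatched featurization vocabularies."""
        try:
            with zipfile.ZipFile(path) as zf:
                meta = json.loads(zf.read("meta.json"))
                weights = np.load(io.BytesIO(zf.read("weights.npz")))
                hist = pd.read_csv(io.BytesIO(zf.read("history.csv")))
        except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, ValueError) as exc:
            raise IncompatibleModelError(f"cannot read model archive {path}: {exc}") from exc
        if meta.get("format") != "molscreen-model-1":
            raise IncompatibleModelError(f"unknown model format in {path}")
        if meta["feature_spec"] != FEATURE_SPEC:
            raise IncompatibleModelError(
                f"model {path} featurized under {meta['feature_spec']!r}, "
                f"current vocabulary is {FEATURE_SPEC!r}"
            )
        cfg_d = meta["config"]
        cfg_d["hidden_layers"] = tuple(cfg_d["hidden_layers"])
        return cls(
            target=meta["target"],
            params=MPNNParams({k: weights[k] for k in weights.files}),
            config=ModelConfig(**cfg_d),
            training_history=hist,
            feature_spec=meta["feature_spec"],
            best_epoch=meta["best_epoch"],
            seeds=meta.get("seeds", {}),
        )


def train_model(
    train: LabeledDataset, valid: LabeledDataset | None, cfg: ModelConfig
) -> AffinityResults:
    """Functional wrapper: fit an :class:`AffinityModel` in one call."""
    return AffinityModel(train, valid, cfg).fit()


def save_model(results: AffinityResults, path: str | Path) -> None:
    results.save(path)


def load_model(path: str | Path) -> AffinityResults:
    return AffinityResults.load(path)
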