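"""Channel selection from learned attention weights.

The selection loop: train the full-channel network, average the CA layer's
per-sample attention vectors over the training set to get one importance
weight per electrode, rank electrodes by descending weight, take the first
``N_c`` as the subset, restrict the data to those electrodes, rebuild the
network for ``N_c`` channels and retrain from scratch.

Because the CA attention is input-dependent (it is a function of the pooled
descriptor of each sample), "the learned channel weight" is defined as the
EXPECTED attention — the mean of per-sample attention vectors over a dataset.
An alternative ordering by the row norms of the CA weight matrix is available
as a diagnostic (``method="weight_norm"``) but is not the default.

A statsmodels-style surface wraps the loop: build a
:class:`ChannelSelectionModel` from a :class:`~ecaselect.preprocess.SampleSet`,
call :meth:`~ChannelSelectionModel.fit`, and read the ranking, weights and
summary off the returned :class:`ChannelSelectionResults`.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .network import (
    Hyperparameters,
    NetworkSpec,
    TrainedModel,
    build_eca_deepnet,
    train_model,
)
from .preprocess import SampleSet

__all__ = [
    "ChannelRanking",
    "ChannelSubset",
    "extract_channel_weights",
    "rank_channels",
    "select_subset",
    "restrict_to_subset",
    "evaluate",
    "channel_sweep",
    "split_by_trial",
    "ChannelSelectionModel",
    "ChannelSelectionResults",
]


@dataclass
class ChannelRanking:
    """Channels ordered by descending importance weight."""

    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        weights = [w for _, w in self.entries]
        if any(w2 > w1 for w1, w2 in zip(weights, weights[1:])):
            raise ValueError("ranking weights must be non-increasing")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.entries])

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.entries) + 1),
                "channel_name": self.names,
                "mean_weight": self.weights,
            }
        )


@dataclass
class ChannelSubset:
    """The first ``n_c`` channels of a ranking, in ranking order."""

    n_c: int
    channels: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_c != len(self.channels):
            raise ValueError("n_c must equal the number of channels")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("subset contains duplicate channels")

    def to_json(self) -> str:
        return json.dumps(
            {"n_c": self.n_c, "channels": self.channels, "provenance": self.provenance}
        )

    def save(self, path: str) -> None:
        """Plain text, one channel name per line (JSON via :meth:`to_json`)."""
        with open(path, "w") as f:
            f.write("\n".join(self.channels) + "\n")


def extract_channel_weights(
    model: TrainedModel,
    samples: SampleSet,
    method: str = "attention",
    return_dispersion: bool = False,
):
    """Per-channel importance weights from a trained model.

    ``method="attention"`` (default): the per-sample CA-layer attention
    vectors over all provided samples, averaged elementwise; entries lie in
    (0, 1).  ``method="weight_norm"``: a diagnostic static ordering from the
    row L2 norms of the CA weight matrix, squashed through a sigmoid of the
    standardized norms so it shares the (0, 1) range — only the order is
    meaningful.
    """
    if model.channel_count != samples.n_channels:
        raise ValueError(
            f"model expects {model.channel_count} channels, samples have "
            f"{samples.n_channels}"
        )
    if method == "attention":
        att = model.attention_vectors(samples.samples)
        w = att.mean(axis=0)
        disp = att.std(axis=0)
    elif method == "weight_norm":
        ca = model.runtime.ca_layer
        if ca is None:
            raise ValueError("this network was built without a CA layer")
        norms = np.linalg.norm(ca.w.value, axis=1)
        sd = norms.std() or 1.0
        w = expit((norms - norms.mean()) / sd)
        disp = np.zeros_like(w)
    else:
        raise ValueError(f"unknown weight extraction method {method!r}")
    return (w, disp) if return_dispersion else w


def rank_channels(w: np.ndarray, names: list[str]) -> ChannelRanking:
    """Sort channels by descending weight; ties keep the lower original index."""
    w = np.asarray(w, dtype=float)
    if w.shape != (len(names),):
        raise ValueError("weight vector length must equal the channel-name count")
    order = np.argsort(-w, kind="stable")
    return ChannelRanking([(names[i], float(w[i])) for i in order])


def select_subset(ranking: ChannelRanking, n_c: int) -> ChannelSubset:
    """The first ``n_c`` channels of the ranking, order preserved."""
    if not (1 <= n_c <= len(ranking)):
        raise ValueError(f"n_c must lie in [1, {len(ranking)}], got {n_c}")
    return ChannelSubset(n_c, ranking.names[:n_c])


def restrict_to_subset(samples: SampleSet, subset: ChannelSubset) -> SampleSet:
    """Keep only the subset's channels, rows ordered as in the subset."""
    index = {n: i for i, n in enumerate(samples.channel_names)}
    missing = [n for n in subset.channels if n not in index]
    if missing:
        raise KeyError(f"channels not present in the sample set: {missing}")
    rows = [index[n] for n in subset.channels]
    return SampleSet(
        samples.samples[:, rows, :], samples.labels, samples.trial_ids, list(subset.channels)
    )


def evaluate(model: TrainedModel, samples: SampleSet, vote_by_trial: bool = False) -> float:
    """Classification accuracy on a sample set.

    Per-crop by default; with ``vote_by_trial`` each trial is scored once by
    the majority vote of its crops (ties resolved toward the smaller label).
    """
    if len(samples) == 0:
        raise ValueError("cannot evaluate on an empty sample set")
    preds = model.predict(samples.samples)
    if not vote_by_trial:
        return float((preds == samples.labels).mean())
    correct = total = 0
    for tid in np.unique(samples.trial_ids):
        m = samples.trial_ids == tid
        votes, counts = np.unique(preds[m], return_counts=True)
        winner = votes[np.argmax(counts)]
        correct += int(winner == samples.labels[m][0])
        total += 1
    return correct / total


def split_by_trial(
    samples: SampleSet, test_fraction: float = 0.2, seed: int = 0
) -> tuple[SampleSet, SampleSet]:
    """Split crops into train/test sets by source trial (no trial straddles)."""
    trials = np.unique(samples.trial_ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(trials)
    n_test = max(1, int(round(test_fraction * trials.size)))
    test_set = set(trials[:n_test].tolist())
    mask = np.array([t in test_set for t in samples.trial_ids])

    def take(m):
        return SampleSet(
            samples.samples[m], samples.labels[m], samples.trial_ids[m], samples.channel_names
        )

    return take(~mask), take(mask)


def _montage_order(subset: ChannelSubset, channel_names: list[str]) -> ChannelSubset:
    index = {n: i for i, n in enumerate(channel_names)}
    ordered = sorted(subset.channels, key=lambda n: index[n])
    return ChannelSubset(subset.n_c, ordered, dict(subset.provenance))


def _spec_like(base: NetworkSpec, channels: int, classes: int) -> NetworkSpec:
    return build_eca_deepnet(
        channels,
        base.time_samples,
        classes,
        filters=base.filters,
        temporal_kernel=base.temporal_kernel,
        pool_size=base.pool_size,
        include_ca_layer=base.include_ca_layer,
    )


def channel_sweep(
    samples: SampleSet,
    hp: Hyperparameters | None = None,
    sizes: list[int] | None = None,
    eval_samples: SampleSet | None = None,
    spec: NetworkSpec | None = None,
    weight_method: str = "attention",
) -> pd.DataFrame:
    """Accuracy and prediction time as a function of subset size.

    Trains the full-channel network once, ranks channels from its CA
    attention, then for each requested size restricts the data to the
    ranking prefix (channels kept in original montage order, so the full-size
    sweep is bit-identical to a direct full-channel run), rebuilds the
    network for that channel count, retrains with the same seed, and scores
    held-out accuracy.  When no held-out set is given, 20% of trials are
    held out (seeded split).  Prediction time is wall-clock and
    hardware-dependent.
    """
    hp = hp or Hyperparameters()
    if eval_samples is None:
        samples, eval_samples = split_by_trial(samples, 0.2, seed=hp.seed)
    c = samples.n_channels
    sizes = sizes or [c]
    if any(not (1 <= s <= c) for s in sizes):
        raise ValueError(f"sizes must lie in [1, {c}]")
    classes = int(np.unique(samples.labels).size)
    if spec is None:
        spec = build_eca_deepnet(c, samples.n_times, classes)
    full_model = train_model(samples, hp, spec=spec)
    w = extract_channel_weights(full_model, samples, method=weight_method)
    ranking = rank_channels(w, samples.channel_names)

    rows = []
    for n_c in sizes:
        subset = _montage_order(select_subset(ranking, n_c), samples.channel_names)
        tr = restrict_to_subset(samples, subset)
        ev = restrict_to_subset(eval_samples, subset)
        sub_spec = _spec_like(spec, n_c, classes)
        model = train_model(tr, hp, spec=sub_spec)
        t0 = time.perf_counter()
        acc = evaluate(model, ev)
        dt = time.perf_counter() - t0
        rows.append({"n_c": n_c, "accuracy": acc, "prediction_time_s": dt})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results surface


class ChannelSelectionModel:
    """Channel selection posed as a model fitted to cropped EEG samples.

    Parameters
    ----------
    samples : SampleSet
        Training crops.
    hp : Hyperparameters, optional
    val_samples : SampleSet, optional
        Used for early stopping during training.
    spec : NetworkSpec, optional
        Architecture override; defaults to the canonical stack for the data's
        geometry.
    weight_method : str
        How channel weights are read off the trained network (see
        :func:`extract_channel_weights`).
    """

    def __init__(
        self,
        samples: SampleSet,
        hp: Hyperparameters | None = None,
        val_samples: SampleSet | None = None,
        spec: NetworkSpec | None = None,
        weight_method: str = "attention",
    ):
        self.samples = samples
        self.hp = hp or Hyperparameters()
        self.val_samples = val_samples
        self.spec = spec
        self.weight_method = weight_method

    @classmethod
    def from_recording(cls, rec, t_start_s=-0.5, t_end_s=4.0, window_samples=1000, stride_samples=62, **kwargs):
        from .preprocess import bandpass_filter, crop_trials, ema_standardize

        rec = ema_standardize(bandpass_filter(rec, 1.0, 40.0), 0.999)
        ss = crop_trials(rec, t_start_s, t_end_s, window_samples, stride_samples)
        return cls(ss, **kwargs)

    def fit(self) -> "ChannelSelectionResults":
        model = train_model(self.samples, self.hp, spec=self.spec, val_samples=self.val_samples)
        w, disp = extract_channel_weights(
            model, self.samples, method=self.weight_method, return_dispersion=True
        )
        ranking = rank_channels(w, self.samples.channel_names)
        return ChannelSelectionResults(self, model, w, disp, ranking)


class ChannelSelectionResults:
    """Fitted channel-selection results: trained network, weights, ranking."""

    def __init__(self, model_def, trained: TrainedModel, weights, dispersion, ranking):
        self.model_def = model_def
        self.trained = trained
        self.attention_weights = np.asarray(weights)
        self.weight_dispersion = np.asarray(dispersion)
        self.ranking = ranking

    @property
    def channel_names(self) -> list[str]:
        return self.model_def.samples.channel_names

    def select(self, n_c: int) -> ChannelSubset:
        sub = select_subset(self.ranking, n_c)
        sub.provenance = {"seed": self.trained.seed, "weight_method": self.model_def.weight_method}
        return sub

    def sweep(self, sizes: list[int], eval_samples: SampleSet | None = None) -> pd.DataFrame:
        return channel_sweep(
            self.model_def.samples,
            self.model_def.hp,
            sizes,
            eval_samples=eval_samples,
            spec=self.trained.spec,
            weight_method=self.model_def.weight_method,
        )

    def evaluate(self, samples: SampleSet, vote_by_trial: bool = False) -> float:
        return evaluate(self.trained, samples, vote_by_trial)

    def ranking_frame(self) -> pd.DataFrame:
        df = self.ranking.to_frame()
        disp = {n: d for n, d in zip(self.channel_names, self.weight_dispersion)}
        df["weight_std"] = [disp[n] for n in df["channel_name"]]
        return df

    def save_ranking_csv(self, path: str) -> None:
        self.ranking.to_frame().to_csv(path, index=False)

    def save_ranking_json(self, path: str) -> None:
        with open(path, "w") as f:
            json.dump(self.ranking_frame().to_dict(orient="records"), f, indent=1)

    def summary(self) -> str:
        hist = self.trained.history[-1] if self.trained.history else {}
        lines = [
            "Channel selection via CA-layer attention",
            "========================================",
            f"channels: {len(self.channel_names)}   "
            f"samples: {len(self.model_def.samples)}   "
            f"classes: {self.trained.class_values.size}",
            f"network parameters: {self.trained.spec.total_parameters:,}   "
            f"seed: {self.trained.seed}",
            f"epochs run: {len(self.trained.history)}   "
            f"final train acc: {hist.get('train_acc', float('nan')):.3f}",
            "",
            "rank  channel   mean_weight   weight_std",
        ]
        for i, (name, w) in enumerate(self.ranking.entries, start=1):
            sd = self.weight_dispersion[self.channel_names.index(name)]
            lines.append(f"{i:>4}  {name:<8}  {w:>11.4f}  {sd:>11.4f}")
        return "\n".join(lines)
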