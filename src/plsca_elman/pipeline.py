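"""End-to-end PLS-CA-Elman classifier and its comparison baselines.

The shipped default pipeline (stage ordering "Thought 4" of the four
orderings considered in the design) is:

1. standardize the features;
2. PLS feature reduction to ``l`` latent scores (PRESS-selected or fixed);
3. UPGMA clustering (Mahalanobis distance) of the training scores into K
   subclasses;
4. one Elman network expert trained per subclass (Levenberg–Marquardt,
   hidden size from the empirical formula with n = l);
5. at prediction time, route each sample to the nearest subclass center
   (Mahalanobis) and decode its expert's linear output to the nearest
   class value.

Variants drop stages: ``ca_elman`` skips PLS, ``pls_elman`` skips
clustering, ``pca_elman`` replaces PLS by a PCA variance-threshold
reduction, ``elman``/``bp`` are single plain networks.  The alternative
stage orderings (thoughts 1-3) are provided for completeness together
with their documented failure modes: orderings that cluster training and
simulation samples jointly can produce a subclass with no training
members (untrainable), and per-subclass PLS can select different latent
dimensions in different subclasses.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import pls as _pls
from .data import Dataset, StandardizationParams, split, standardize_apply, standardize_fit
from .discriminant import assign_all
from .elman import (
    ElmanNet,
    TrainConfig,
    TrainReport,
    decode_labels,
    hidden_size,
    make_bp_net,
    make_elman_net,
    sse,
    train_lm,
)

__all__ = [
    "PipelineConfig",
    "PipelineModel",
    "EvalResult",
    "VARIANTS",
    "fit",
    "predict",
    "fit_thought_variant",
    "benchmark",
]

VARIANTS = ("plsca_elman", "ca_elman", "pls_elman", "pca_elman", "elman", "bp")


@dataclass
class PipelineConfig:
    variant: str = "plsca_elman"
    thought: int = 4
    k_subclasses: int = 3  # the design recommends 3-6
    lam: float | None = None  # dendrogram height cutoff, alternative to k
    min_subclass_size: int = 3
    pls_l: int | None = None  # None = PRESS auto-selection
    pls_k_folds: int = 10
    pls_max_components: int | None = None
    pca_variance_threshold: float = 0.8
    cov_method: str = "pinv"
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.thought not in (1, 2, 3, 4):
            raise ValueError("thought must be 1, 2, 3 or 4")
        if self.lam is None and not 1 <= self.k_subclasses:
            raise ValueError("k_subclasses must be ≥ 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        train = d.pop("train", d.pop("elman", None))
        cfg = cls(**d)
        if train:
            cfg.train = TrainConfig(**train)
        return cfg


def _expert_seed(seed: int, subclass_id: int) -> int:
    return (int(seed) + 1009 * int(subclass_id)) % (2**31 - 1)


@dataclass
class EvalResult:
    accuracy: float | None  # percent correct, None when labels absent
    sse: float  # Σ (t - y)² over the evaluated set
    training_steps: int | None = None  # total accepted LM epochs over all experts
    runtime_seconds: float | None = None


@dataclass
class PipelineModel:
    cfg: PipelineConfig
    standardization: StandardizationParams
    experts: dict[int, ElmanNet]
    reports: dict[int, TrainReport]
    class_values: np.ndarray | None
    pls: _pls.PLSModel | None = None
    pca: _pls.PCAModel | None = None
    partition: _cluster.SubclassPartition | None = None
    # thought 1/2: one PLS per subclass; thought 1/3: precomputed routing
    per_subclass_pls: dict[int, _pls.PLSModel] | None = None
    fixed_assignment: dict[str, int] | None = None

    @property
    def training_steps(self) -> int:
        return int(sum(r.epochs_run for r in self.reports.values()))

    @property
    def n_subclasses(self) -> int:
        return len(self.experts)


def _reduce_fit(Xs: np.ndarray, y: np.ndarray, cfg: PipelineConfig):
    """Fit the feature-reduction stage for the configured variant."""
    if cfg.variant in ("plsca_elman", "pls_elman"):
        if cfg.pls_l is None:
            l, press = _pls.select_components_cv(
                Xs, y, k_folds=min(cfg.pls_k_folds, Xs.shape[0] // 2),
                max_components=cfg.pls_max_components, seed=cfg.seed,
            )
        else:
            l, press = cfg.pls_l, None
        model = _pls.nipals_fit(Xs, y, max_components=cfg.pls_max_components, l=l)
        model.press = None if press is None else np.asarray(press)
        return model, None, _pls.pls_transform(model, Xs)
    if cfg.variant == "pca_elman":
        model = _pls.pca_fit(Xs, cfg.pca_variance_threshold)
        return None, model, _pls.pca_transform(model, Xs)
    return None, None, Xs


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel 1..K in order of first appearance."""
    out = np.empty_like(labels)
    seen: dict[int, int] = {}
    for i, v in enumerate(labels):
        if v not in seen:
            seen[v] = len(seen) + 1
        out[i] = seen[v]
    return out


def _merge_small(
    F: np.ndarray, labels: np.ndarray, floor: int, V_inv: np.ndarray
) -> np.ndarray:
    """Fold each subclass smaller than ``floor`` into the nearest
    adequately-sized subclass (an untrainably small subclass helps
    nobody), nearest measured center-to-center in Mahalanobis."""
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        big = ids[counts >= floor]
        small = ids[counts < floor]
        if small.size == 0 or len(ids) <= 1:
            break
        if big.size == 0:
            big = ids  # everything is small: fall back to pairwise merging
        centers = {int(i): F[labels == i].mean(axis=0) for i in ids}
        s = int(small[np.argmin(counts[np.isin(ids, small)])])
        cand = [int(o) for o in big if o != s]
        if not cand:
            break
        d = [_cluster.mahalanobis(centers[s], centers[o], V_inv) for o in cand]
        labels[labels == s] = cand[int(np.argmin(d))]
    return labels


def _guarded_cut(
    F: np.ndarray,
    tree: _cluster.MergeTree,
    cfg: PipelineConfig,
    V_inv: np.ndarray,
) -> np.ndarray:
    """Cut the tree and apply the minimum-subclass-size guard.

    With the k rule, folding an undersized splinter into its nearest
    subclass would leave fewer than the requested K groups, so the tree
    is re-cut one level deeper until K adequately-sized subclasses
    remain (or the tree is exhausted).  With the λ rule the cut height
    is authoritative and splinters are simply folded in.
    """
    floor = cfg.min_subclass_size
    if cfg.lam is not None:
        labels = _cluster.cut_tree(tree, lam=cfg.lam)
        return _compact_labels(_merge_small(F, labels, floor, V_inv))
    k = cfg.k_subclasses
    n = tree.leaf_count
    labels = _cluster.cut_tree(tree, k=min(k, n))
    for kp in range(min(k, n), n + 1):
        trial = _merge_small(F, _cluster.cut_tree(tree, k=kp), floor, V_inv)
        labels = trial
        if np.unique(trial).size >= k:
            break
    # a deeper cut can overshoot: merge closest centers back down to K
    while np.unique(labels).size > k:
        ids = np.unique(labels)
        centers = {int(i): F[labels == i].mean(axis=0) for i in ids}
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = int(ids[ai]), int(ids[bi])
                d = _cluster.mahalanobis(centers[a], centers[b], V_inv)
                if best is None or d < best[0]:
                    best = (d, a, b)
        labels = labels.copy()
        labels[labels == best[2]] = best[1]
    return _compact_labels(labels)


def _partition_fit(F: np.ndarray, cfg: PipelineConfig) -> _cluster.SubclassPartition:
    V = _cluster.pooled_covariance(F)
    V_inv = _cluster.inverse_covariance(V, method=cfg.cov_method)
    D = _cluster.pairwise_mahalanobis(F, V_inv)
    tree = _cluster.upgma_linkage(D)
    labels = _guarded_cut(F, tree, cfg, V_inv)
    cut = cfg.lam if cfg.lam is not None else cfg.k_subclasses
    return _cluster.partition_summarize(F, labels, cov_method=cfg.cov_method, cut_value=cut)


def _train_experts(
    F: np.ndarray,
    y: np.ndarray,
    labels: np.ndarray,
    cfg: PipelineConfig,
) -> tuple[dict[int, ElmanNet], dict[int, TrainReport]]:
    experts: dict[int, ElmanNet] = {}
    reports: dict[int, TrainReport] = {}
    n_in = F.shape[1]
    r = hidden_size(n_in, 1)
    maker = make_bp_net if cfg.variant == "bp" else make_elman_net
    for k in sorted(np.unique(labels)):
        members = labels == k
        net = maker(n_in, r, 1, seed=_expert_seed(cfg.seed, k))
        tc = replace(cfg.train, seed=_expert_seed(cfg.seed, k))
        reports[int(k)] = train_lm(net, F[members], y[members, None], tc)
        experts[int(k)] = net
    return experts, reports


def fit(
    train: Dataset,
    cfg: PipelineConfig | None = None,
    standardization: StandardizationParams | None = None,
) -> PipelineModel:
    """Fit the configured variant on a training set.

    ``standardization`` lets the caller supply pooled (pre-split)
    statistics — the convention of standardizing the original data before
    dividing it; by default statistics are fitted on the training set.
    """
    cfg = cfg or PipelineConfig()
    if train.y is None:
        raise ValueError("training data must carry labels")
    if np.unique(train.y).size < 2:
        raise ValueError("training data must contain at least 2 classes")
    std = standardization or standardize_fit(train)
    Xs = standardize_apply(train.X, std)
    try:
        pls_model, pca_model, F = _reduce_fit(Xs, train.y, cfg)
    except Exception as err:  # surface the stage that failed
        raise RuntimeError(f"feature-reduction stage failed: {err}") from err

    partition = None
    labels = np.ones(train.n_samples, dtype=int)
    if cfg.variant in ("plsca_elman", "ca_elman"):
        try:
            partition = _partition_fit(F, cfg)
        except Exception as err:
            raise RuntimeError(f"clustering stage failed: {err}") from err
        labels = partition.assignment

    experts, reports = _train_experts(F, train.y, labels, cfg)
    return PipelineModel(
        cfg=cfg,
        standardization=std,
        experts=experts,
        reports=reports,
        class_values=np.unique(train.y),
        pls=pls_model,
        pca=pca_model,
        partition=partition,
    )


def _reduce_apply(model: PipelineModel, Xs: np.ndarray) -> np.ndarray:
    if model.pls is not None:
        return _pls.pls_transform(model.pls, Xs)
    if model.pca is not None:
        return _pls.pca_transform(model.pca, Xs)
    return Xs


def predict(
    model: PipelineModel, sim: Dataset, return_routing: bool = False
):
    """Classify a simulation set; returns (labels, EvalResult).

    Raw network outputs feed the SSE metric; decoded nearest-class labels
    feed the accuracy.  When the simulation set has no labels the
    EvalResult carries accuracy=None.
    """
    t0 = time.perf_counter()
    Xs = standardize_apply(sim.X, model.standardization)

    if model.fixed_assignment is not None:
        try:
            ids = np.array([model.fixed_assignment[s] for s in sim.sample_ids])
        except KeyError as err:
            raise ValueError(
                f"sample {err} was not part of the jointly-clustered data; "
                "thought-1/3 models can only evaluate the samples they clustered"
            ) from err
    elif model.partition is not None:
        F_route = Xs if model.per_subclass_pls is not None else _reduce_apply(model, Xs)
        ids, _ = assign_all(F_route, model.partition)
    else:
        ids = np.ones(sim.n_samples, dtype=int)

    outputs = np.empty(sim.n_samples)
    for k, net in model.experts.items():
        members = ids == k
        if not members.any():
            continue
        if model.per_subclass_pls is not None:
            Fk = _pls.pls_transform(model.per_subclass_pls[k], Xs[members])
        else:
            Fk = _reduce_apply(model, Xs[members])
        outputs[members] = net.predict(Fk, context_mode=model.cfg.train.context_mode)[:, 0]

    labels = (
        decode_labels(outputs, model.class_values)
        if model.class_values is not None
        else outputs.copy()
    )
    runtime = time.perf_counter() - t0
    if sim.y is not None:
        acc = 100.0 * float(np.mean(labels == sim.y))
        err = sse(sim.y, outputs)
    else:
        acc, err = None, float("nan")
    result = EvalResult(
        accuracy=acc,
        sse=err,
        training_steps=model.training_steps,
        runtime_seconds=runtime,
    )
    if return_routing:
        return labels, result, ids
    return labels, result


# ---------------------------------------------------------------------
# alternative stage orderings (thoughts 1-3) and the pooled-standardization
# pooled-standardization entry point for thought 4


def fit_thought_variant(
    full: Dataset, n_train: int, thought: int, cfg: PipelineConfig | None = None
) -> tuple[PipelineModel, Dataset, Dataset]:
    """Fit one of the four stage orderings on pre-split data.

    Returns (model, train set, simulation set).  Thought 4 is the shipped
    default ordering; 1-3 are the documented alternatives with their
    failure modes surfaced as errors/warnings rather than silently fixed.
    """
    cfg = cfg or PipelineConfig()
    cfg = replace(cfg, thought=thought)
    if full.y is None:
        raise ValueError("thought variants need labels for the full data")
    std = standardize_fit(full)
    train, sim = split(full, train_count=n_train)

    if thought == 4:
        model = fit(train, cfg, standardization=std)
        return model, train, sim

    Xs_full = standardize_apply(full.X, std)
    train_mask = np.zeros(full.n_samples, dtype=bool)
    train_mask[:n_train] = True

    if thought in (1, 3):
        # cluster ALL samples jointly (training + simulation)
        if thought == 3:
            # global PLS first, cluster in score space
            if cfg.pls_l is None:
                l, _ = _pls.select_components_cv(
                    Xs_full[train_mask], full.y[:n_train],
                    k_folds=min(cfg.pls_k_folds, n_train // 2), seed=cfg.seed,
                )
            else:
                l = cfg.pls_l
            pls_model = _pls.nipals_fit(Xs_full[train_mask], full.y[:n_train], l=l)
            F_full = _pls.pls_transform(pls_model, Xs_full)
        else:
            pls_model = None
            F_full = Xs_full
        part = _partition_fit(F_full, replace(cfg, min_subclass_size=1))
        labels_all = part.assignment
        for k in np.unique(labels_all):
            if not np.any(labels_all[train_mask] == k):
                raise ValueError(
                    f"subclass {int(k)} contains no training samples; "
                    "the network for it cannot be trained (known failure mode "
                    "of clustering training and simulation samples jointly)"
                )
        per_subclass_pls = None
        if thought == 1:
            # PLS per subclass, fitted on that subclass's training members
            per_subclass_pls = {}
            F_list = {}
            for k in np.unique(labels_all):
                m = (labels_all == k) & train_mask
                pk = _pls.nipals_fit(Xs_full[m], full.y[m], l=cfg.pls_l)
                per_subclass_pls[int(k)] = pk
                F_list[int(k)] = _pls.pls_transform(pk, Xs_full)
            dims = {k: p.l for k, p in per_subclass_pls.items()}
            if len(set(dims.values())) > 1:
                warnings.warn(
                    f"per-subclass PLS selected different dimensions {dims}; "
                    "subclass feature spaces are out of step"
                )
            experts, reports = {}, {}
            for k in sorted(per_subclass_pls):
                m = (labels_all == k) & train_mask
                Fk = _pls.pls_transform(per_subclass_pls[k], Xs_full[m])
                net = make_elman_net(
                    Fk.shape[1], hidden_size(Fk.shape[1], 1), 1,
                    seed=_expert_seed(cfg.seed, k),
                )
                tc = replace(cfg.train, seed=_expert_seed(cfg.seed, k))
                reports[k] = train_lm(net, Fk, full.y[m, None], tc)
                experts[k] = net
        else:
            experts, reports = _train_experts(
                F_full[train_mask], full.y[:n_train], labels_all[train_mask], cfg
            )
        fixed = {sid: int(k) for sid, k in zip(full.sample_ids, labels_all)}
        model = PipelineModel(
            cfg=cfg,
            standardization=std,
            experts=experts,
            reports=reports,
            class_values=np.unique(full.y[:n_train]),
            pls=pls_model,
            partition=part,
            per_subclass_pls=per_subclass_pls,
            fixed_assignment=fixed,
        )
        return model, train, sim

    # thought 2: cluster the training samples in raw standardized space,
    # then per-subclass PLS (dimensions may disagree across subclasses)
    Xs_train = Xs_full[train_mask]
    part = _partition_fit(Xs_train, cfg)
    labels = part.assignment
    per_subclass_pls = {}
    for k in np.unique(labels):
        m = labels == k
        per_subclass_pls[int(k)] = _pls.nipals_fit(
            Xs_train[m], full.y[:n_train][m], l=cfg.pls_l
        )
    dims = {k: p.l for k, p in per_subclass_pls.items()}
    if len(set(dims.values())) > 1:
        warnings.warn(
            f"per-subclass PLS selected different dimensions {dims}; "
            "subclass feature spaces are out of step"
        )
    experts, reports = {}, {}
    for k in sorted(per_subclass_pls):
        m = labels == k
        Fk = _pls.pls_transform(per_subclass_pls[k], Xs_train[m])
        net = make_elman_net(
            Fk.shape[1], hidden_size(Fk.shape[1], 1), 1, seed=_expert_seed(cfg.seed, k)
        )
        tc = replace(cfg.train, seed=_expert_seed(cfg.seed, k))
        reports[k] = train_lm(net, Fk, full.y[:n_train][m, None], tc)
        experts[k] = net
    model = PipelineModel(
        cfg=cfg,
        standardization=std,
        experts=experts,
        reports=reports,
        class_values=np.unique(full.y[:n_train]),
        partition=part,
        per_subclass_pls=per_subclass_pls,
    )
    return model, train, sim


# ---------------------------------------------------------------------


def benchmark(
    train: Dataset,
    sim: Dataset,
    variants: list[str] | tuple[str, ...] = VARIANTS,
    seeds: list[int] | tuple[int, ...] = (0,),
    base_cfg: PipelineConfig | None = None,
    standardization: StandardizationParams | None = None,
) -> pd.DataFrame:
    """Run every variant × seed and tabulate accuracy / training steps /
    run time / SSE, plus one mean row per variant.

    A variant that errors is recorded with NaN metrics; the remaining
    variants still run.
    """
    if not variants:
        raise ValueError("need at least one variant")
    base_cfg = base_cfg or PipelineConfig()
    rows = []
    for variant in variants:
        for seed in seeds:
            cfg = replace(base_cfg, variant=variant, seed=int(seed))
            t0 = time.perf_counter()
            try:
                model = fit(train, cfg, standardization=standardization)
                fit_time = time.perf_counter() - t0
                _, res = predict(model, sim)
                rows.append(
                    {
                        "variant": variant,
                        "seed": int(seed),
                        "accuracy": res.accuracy,
                        "training_steps": res.training_steps,
                        "run_time_s": fit_time + (res.runtime_seconds or 0.0),
                        "sse": res.sse,
                    }
                )
            except Exception as err:
                warnings.warn(f"variant {variant} (seed {seed}) failed: {err}")
                rows.append(
                    {
                        "variant": variant,
                        "seed": int(seed),
                        "accuracy": np.nan,
                        "training_steps": np.nan,
                        "run_time_s": np.nan,
                        "sse": np.nan,
                    }
                )
    df = pd.DataFrame(rows)
    means = (
        df.groupby("variant", sort=False)[["accuracy", "training_steps", "run_time_s", "sse"]]
        .mean()
        .reset_index()
    )
    means.insert(1, "seed", "mean")
    return pd.concat([df, means], ignore_index=True)


def format_benchmark(df: pd.DataFrame) -> str:
    """Printable table in the shape of the published comparisons; training
    steps are left blank for the cluster-wise variants (many small expert
    trainings are not comparable to one monolithic count)."""
    show = df.copy()
    ca = show["variant"].isin(["plsca_elman", "ca_elman"])
    show.loc[ca, "training_steps"] = np.nan
    show["training_steps"] = show["training_steps"].map(
        lambda v: "—" if pd.isna(v) else f"{v:.0f}"
    )
    show["accuracy"] = show["accuracy"].map(
        lambda v: "" if pd.isna(v) else f"{v:.2f}"
    )
    show["sse"] = show["sse"].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
    show["run_time_s"] = show["run_time_s"].map(
        lambda v: "" if pd.isna(v) else f"{v:.2f}"
    )
    return show.to_string(index=False)


def save_model(model: PipelineModel, path) -> None:
    """Serialize a fitted pipeline to a JSON container."""
    payload = {
        "cfg": {
            **{
                k: getattr(model.cfg, k)
                for k in (
                    "variant", "thought", "k_subclasses", "lam", "min_subclass_size",
                    "pls_l", "pls_k_folds", "pls_max_components",
                    "pca_variance_threshold", "cov_method", "seed",
                )
            },
            "train": model.cfg.train.__dict__,
        },
        "standardization": {
            "means": model.standardization.means.tolist(),
            "scales": model.standardization.scales.tolist(),
        },
        "class_values": None
        if model.class_values is None
        else model.class_values.tolist(),
        "experts": {str(k): net.to_dict() for k, net in model.experts.items()},
        "partition": None
        if model.partition is None
        else {
            "assignment": model.partition.assignment.tolist(),
            "centers": model.partition.centers.tolist(),
            "pooled_inverse_covariance": model.partition.pooled_inverse_covariance.tolist(),
            "cut_value": model.partition.cut_value,
        },
        "pls": None,
        "pca": None,
    }
    if model.pls is not None:
        payload["pls"] = {
            k: getattr(model.pls, k).tolist()
            for k in ("T", "P", "U", "Q", "W", "inner_coefs",
                      "x_means", "x_scales", "y_means", "y_scales")
        }
        payload["pls"]["l"] = model.pls.l
        payload["pls"]["achieved"] = model.pls.achieved
    if model.pca is not None:
        payload["pca"] = {
            "components": model.pca.components.tolist(),
            "explained_variance_ratio": model.pca.explained_variance_ratio.tolist(),
            "k": model.pca.k,
            "means": model.pca.means.tolist(),
            "scales": model.pca.scales.tolist(),
        }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> PipelineModel:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = PipelineConfig.from_dict(payload["cfg"])
    std = StandardizationParams(
        means=np.asarray(payload["standardization"]["means"]),
        scales=np.asarray(payload["standardization"]["scales"]),
    )
    experts = {int(k): ElmanNet.from_dict(d) for k, d in payload["experts"].items()}
    partition = None
    if payload["partition"] is not None:
        p = payload["partition"]
        partition = _cluster.SubclassPartition(
            assignment=np.asarray(p["assignment"], dtype=int),
            centers=np.asarray(p["centers"], dtype=float),
            pooled_inverse_covariance=np.asarray(
                p["pooled_inverse_covariance"], dtype=float
            ),
            cut_value=p["cut_value"],
        )
    pls_model = None
    if payload["pls"] is not None:
        p = payload["pls"]
        pls_model = _pls.PLSModel(
            T=np.asarray(p["T"]), P=np.asarray(p["P"]), U=np.asarray(p["U"]),
            Q=np.asarray(p["Q"]), W=np.asarray(p["W"]),
            inner_coefs=np.asarray(p["inner_coefs"]),
            l=int(p["l"]), achieved=int(p["achieved"]),
            x_means=np.asarray(p["x_means"]), x_scales=np.asarray(p["x_scales"]),
            y_means=np.asarray(p["y_means"]), y_scales=np.asarray(p["y_scales"]),
        )
    pca_model = None
    if payload["pca"] is not None:
        p = payload["pca"]
        pca_model = _pls.PCAModel(
            components=np.asarray(p["components"]),
            explained_variance_ratio=np.asarray(p["explained_variance_ratio"]),
            k=int(p["k"]),
            means=np.asarray(p["means"]),
            scales=np.asarray(p["scales"]),
        )
    return PipelineModel(
        cfg=cfg,
        standardization=std,
        experts=experts,
        reports={k: TrainReport(epochs_run=0, final_sse=float("nan")) for k in experts},
        class_values=None
        if payload["class_values"] is None
        else np.asarray(payload["class_values"]),
        pls=pls_model,
        pca=pca_model,
        partition=partition,
    )
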