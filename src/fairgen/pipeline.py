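"""End-to-end experiment orchestration.

One configuration drives the three-step method: (1) train a conditional
diffusion model on the labeled + unlabeled pool, (2) sample a synthetic pool
under the fair policy (uniform attribute, preserved label prevalence),
(3) train downstream classifier arms on real/synthetic mixtures and evaluate
performance and fairness in-distribution and on held-out (out-of-distribution)
domains, over several classifier seeds.

Every stage derives its randomness from the master seed via SeedSequence, so
a re-run with the same config reproduces every reported number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as fm
from .classify import ClassifierConfig, oversample_even, train_classifier
from .cohort import (
    AttributeSpec,
    Cohort,
    CohortConfig,
    Example,
    generate_cohort,
    skew_dataset,
    strip_labels,
)
from .diffusion import (
    ConditioningVector,
    make_noise_schedule,
    sample_ddpm,
    train_diffusion,
)
from .sampling import MixtureConfig, SamplingPolicy, build_mixture_stream, draw_conditioning

__all__ = ["ExperimentConfig", "load_config", "run_experiment", "ARMS"]

ARMS = ("baseline", "augment", "oversample", "focal", "synthetic", "synthetic_augment")


@dataclass(frozen=True)
class ExperimentConfig:
    cohort: CohortConfig
    property_name: str
    ood_domains: tuple = ()
    eval_fraction: float = 0.3
    unlabeled_fraction: float = 0.3
    # fraction of held-out-domain examples contributed, label-stripped, to the
    # unlabeled diffusion pool (never to any classifier stream or eval set);
    # off by default at this scale
    ood_unlabeled_fraction: float = 0.0
    skew_cap: int | None = None
    conditioning: str = "label+property"  # or "label"
    alpha: float = 0.25
    pool_size: int | None = None
    stream_size: int | None = None
    arms: tuple = ("baseline", "synthetic")
    seeds: tuple = (0, 1, 2, 3, 4)
    augment_policy: str = "histopathology"
    focal_gamma: float = 2.0
    guidance_weight: float = 0.0
    high_risk_labels: tuple = ()
    diffusion: dict = field(
        default_factory=lambda: {
            "T": 100,
            "steps": 3000,
            "batch_size": 64,
            "lr": 1e-3,
            "hidden": (256, 256),
            "uncond_prob": 0.1,
            "schedule": "cosine",
        }
    )
    classifier: dict = field(
        default_factory=lambda: {
            "steps": 600,
            "batch_size": 32,
            "learning_rate": 1e-3,
            "hidden": (128, 64),
        }
    )
    seed: int = 0

    def __post_init__(self):
        if self.conditioning not in ("label", "label+property"):
            raise ValueError(f"unknown conditioning mode {self.conditioning!r}")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")
        if any(d >= self.cohort.n_domains or d < 0 for d in self.ood_domains):
            raise ValueError("ood_domains must be valid domain ids")
        if len(self.ood_domains) >= self.cohort.n_domains:
            raise ValueError("at least one domain must remain in-distribution")
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown arms: {sorted(unknown)}")
        names = [a.name for a in self.cohort.attributes]
        if self.property_name not in names:
            raise ValueError(
                f"property_name {self.property_name!r} not among cohort attributes {names}"
            )


_CONFIG_KEYS = {
    "cohort",
    "property_name",
    "ood_domains",
    "eval_fraction",
    "unlabeled_fraction",
    "ood_unlabeled_fraction",
    "skew_cap",
    "conditioning",
    "alpha",
    "pool_size",
    "stream_size",
    "arms",
    "seeds",
    "augment_policy",
    "focal_gamma",
    "guidance_weight",
    "high_risk_labels",
    "diffusion",
    "classifier",
    "seed",
}


def config_from_dict(raw: dict) -> ExperimentConfig:
    raw = dict(raw)
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    craw = dict(raw.pop("cohort"))
    attrs = tuple(
        AttributeSpec(
            name=a["name"],
            values=tuple(a["values"]),
            table=tuple(tuple(r) for r in a["table"]),
        )
        for a in craw.pop("attributes", [])
    )
    if "label_prevalence" in craw:
        craw["label_prevalence"] = tuple(craw["label_prevalence"])
    if "domain_effect" in craw:
        craw["domain_effect"] = tuple(tuple(r) for r in craw["domain_effect"])
    cohort_cfg = CohortConfig(attributes=attrs, **craw)
    for key in ("ood_domains", "arms", "seeds", "high_risk_labels"):
        if key in raw:
            raw[key] = tuple(raw[key])
    for key in ("diffusion", "classifier"):
        if key in raw:
            base = dict(getattr(ExperimentConfig, "__dataclass_fields__")[key].default_factory())
            base.update(raw[key])
            if "hidden" in base:
                base["hidden"] = tuple(base["hidden"])
            raw[key] = base
    return ExperimentConfig(cohort=cohort_cfg, **raw)


def load_config(path) -> ExperimentConfig:
    """Parse an experiment YAML, fill defaults, reject unknown keys."""
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw)


def dump_config(config: ExperimentConfig) -> str:
    d = asdict(config)
    return yaml.safe_dump(json.loads(json.dumps(d, default=list)), sort_keys=True)


def config_hash(config: ExperimentConfig) -> str:
    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:16]


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _conditioning_for(example, n_labels, n_prop, prop_values, prop_name, mode):
    label = example.label if example.labeled else None
    if example.labeled and example.soft_label is not None and label is None:
        label = np.asarray(example.soft_label)
    prop_index = None
    if mode == "label+property" and prop_name in example.attributes:
        prop_index = list(prop_values).index(example.attributes[prop_name])
    return ConditioningVector.for_label(
        label, n_labels, prop_index=prop_index, n_prop=n_prop if mode == "label+property" else 0
    )


def _split_cohort(cohort: Cohort, config: ExperimentConfig, rng: np.random.Generator):
    """Deterministic split.  In-distribution examples divide into a training
    pool and a held-out evaluation set.  Held-out-domain examples divide into
    an OOD evaluation set and (optionally) a label-stripped contribution to
    the unlabeled diffusion pool — labels from OOD domains are never used for
    training anything."""
    ood_idx = [i for i, e in enumerate(cohort.examples) if e.domain in config.ood_domains]
    id_idx = [i for i, e in enumerate(cohort.examples) if e.domain not in config.ood_domains]
    perm = rng.permutation(len(id_idx))
    n_eval = int(round(config.eval_fraction * len(id_idx)))
    eval_id = [id_idx[i] for i in perm[:n_eval]]
    train = [id_idx[i] for i in perm[n_eval:]]
    operm = rng.permutation(len(ood_idx))
    n_pool = int(round(config.ood_unlabeled_fraction * len(ood_idx)))
    ood_pool = [ood_idx[i] for i in operm[:n_pool]]
    eval_ood = [ood_idx[i] for i in operm[n_pool:]]
    return (
        cohort.subset(train),
        cohort.subset(sorted(eval_id)),
        cohort.subset(sorted(eval_ood)),
        cohort.subset(sorted(ood_pool)),
    )


def _sample_pool(model, policy, config, prop_values, n, seed) -> Cohort:
    conds = draw_conditioning(policy, n, seed)
    n_labels = config.cohort.n_labels
    n_prop = len(prop_values) if config.conditioning == "label+property" else 0
    cond_mat = np.zeros((n, n_labels + n_prop))
    for i, (y, a) in enumerate(conds):
        cond_mat[i, y] = 1.0
        if n_prop:
            cond_mat[i, n_labels + list(prop_values).index(a)] = 1.0
    imgs = sample_ddpm(model, cond_mat, w=config.guidance_weight, seed=seed, n=n)
    imgs = (imgs + 1.0) / 2.0
    examples = []
    for i, (y, a) in enumerate(conds):
        attrs = {config.property_name: a} if n_prop else {}
        examples.append(
            Example(
                image=imgs[i].astype(np.float32),
                label=int(y),
                soft_label=None,
                attributes=attrs,
                domain=-1,
                labeled=True,
                synthetic=True,
                example_id=f"synthetic-{i:06d}",
            )
        )
    return Cohort(examples, config.cohort, None)


def _build_stream(arm, labeled, pool, config, n_stream, seed):
    if arm in ("synthetic", "synthetic_augment"):
        return build_mixture_stream(
            labeled, pool, MixtureConfig(config.alpha), n_stream, seed
        )
    if arm == "oversample":
        return oversample_even(labeled, config.property_name, seed).labeled_examples()
    return labeled.labeled_examples()


def _evaluate(clf, eval_cohort: Cohort, config: ExperimentConfig) -> dict:
    examples = eval_cohort.labeled_examples()
    images = np.stack([e.image for e in examples])
    reference = np.array([e.label for e in examples])
    groups = np.array([e.attributes[config.property_name] for e in examples])
    probs = clf.predict_proba(images)
    preds = probs.argmax(axis=1)
    out = {
        "accuracy": float(np.mean(preds == reference)),
        "balanced_accuracy": fm.balanced_accuracy(preds, reference),
    }
    rep = fm.subgroup_report(
        "accuracy",
        lambda predictions, reference: float(np.mean(predictions == reference)),
        groups,
        predictions=preds,
        reference=reference,
    )
    out["subgroup_accuracy"] = {str(k): v for k, v in rep.per_group.items()}
    out["subgroup_gap"] = rep.gap
    if config.cohort.n_labels == 2:
        scores = probs[:, 1]
        try:
            out["auc"] = fm.auc(scores, reference)
        except fm.UndefinedMetricError:
            pass
        if len(np.unique(groups)) == 2:
            try:
                out["auc_gap"] = fm.auc_gap(scores, reference, groups)
            except fm.UndefinedMetricError:
                pass
    if config.high_risk_labels:
        try:
            out["high_risk_sensitivity"] = fm.high_risk_sensitivity(
                preds, reference, config.high_risk_labels
            )
        except fm.UndefinedMetricError:
            pass
    return out


def run_experiment(config: ExperimentConfig, out_dir=None) -> dict:
    """Execute the full three-step method and return the experiment report.

    Stages: generate cohort -> hold out OOD domains and an in-distribution
    evaluation split -> strip labels for the unlabeled pool -> skew the
    labeled set -> train the conditional diffusion model -> sample a fair
    synthetic pool -> train every classifier arm across seeds -> evaluate.
    Reported metrics are per-seed plus mean and sd.
    """
    ss = np.random.SeedSequence(config.seed)
    s_split, s_strip, s_skew, s_diff, s_pool, s_arms = ss.spawn(6)

    cohort = generate_cohort(config.cohort)
    train_pool, eval_id, eval_ood, ood_pool = _split_cohort(
        cohort, config, np.random.default_rng(_derive_seed(s_split))
    )
    eval_ids = {e.example_id for e in eval_id.examples} | {
        e.example_id for e in eval_ood.examples
    }
    train_ids = {e.example_id for e in train_pool.examples} | {
        e.example_id for e in ood_pool.examples
    }
    assert not (train_ids & eval_ids)

    train_pool = strip_labels(
        train_pool, config.unlabeled_fraction, keep_domain=True, seed=_derive_seed(s_strip)
    )
    labeled = train_pool.subset(
        [i for i, e in enumerate(train_pool.examples) if e.labeled]
    )
    if config.skew_cap is not None:
        labeled = skew_dataset(
            labeled, config.property_name, config.skew_cap, _derive_seed(s_skew)
        )
    ood_unlabeled = strip_labels(ood_pool, 1.0, keep_domain=True, seed=0)
    unlabeled = Cohort(
        [e for e in train_pool.examples if not e.labeled] + ood_unlabeled.examples,
        cohort.config,
        cohort.planted_rule,
    )

    prop_spec = next(
        a for a in config.cohort.attributes if a.name == config.property_name
    )
    policy = SamplingPolicy.from_cohort(labeled, config.property_name)

    needs_pool = any(a.startswith("synthetic") for a in config.arms)
    pool = None
    diffusion_model = None
    if needs_pool:
        dcfg = config.diffusion
        schedule = make_noise_schedule(dcfg["T"], dcfg.get("schedule", "cosine"))
        train_examples = labeled.examples + unlabeled.examples
        n_prop = len(prop_spec.values)
        conds = [
            _conditioning_for(
                e,
                config.cohort.n_labels,
                n_prop,
                prop_spec.values,
                config.property_name,
                config.conditioning,
            )
            for e in train_examples
        ]
        diffusion_model = train_diffusion(
            np.stack([e.image for e in train_examples]),
            conds,
            schedule,
            steps=dcfg["steps"],
            batch_size=dcfg["batch_size"],
            lr=dcfg["lr"],
            uncond_prob=dcfg["uncond_prob"],
            hidden=tuple(dcfg["hidden"]),
            seed=_derive_seed(s_diff),
        )
        n_pool = config.pool_size or len(labeled.examples)
        pool = _sample_pool(
            diffusion_model, policy, config, prop_spec.values, n_pool, _derive_seed(s_pool)
        )

    n_stream = config.stream_size or max(2 * len(labeled.examples), 500)
    ccfg = config.classifier
    report = {"config_hash": config_hash(config), "arms": {}, "n": {
        "labeled_train": len(labeled.examples),
        "unlabeled_train": len(unlabeled.examples),
        "eval_in_distribution": len(eval_id.examples),
        "eval_ood": len(eval_ood.examples),
        "synthetic_pool": 0 if pool is None else len(pool.examples),
    }}
    arm_seeds = s_arms.spawn(len(config.arms) * len(config.seeds))
    k = 0
    for arm in config.arms:
        arm_out = {"in_distribution": [], "ood": []}
        for seed in config.seeds:
            run_seed = _derive_seed(arm_seeds[k])
            k += 1
            stream = _build_stream(arm, labeled, pool, config, n_stream, run_seed)
            clf = train_classifier(
                stream,
                ClassifierConfig(
                    n_labels=config.cohort.n_labels,
                    loss="focal" if arm == "focal" else "cross_entropy",
                    gamma=config.focal_gamma,
                    augmentation_policy=config.augment_policy
                    if arm in ("augment", "synthetic_augment")
                    else None,
                    steps=ccfg["steps"],
                    batch_size=ccfg["batch_size"],
                    learning_rate=ccfg["learning_rate"],
                    hidden=tuple(ccfg["hidden"]),
                    seed=run_seed,
                ),
            )
            arm_out["in_distribution"].append(_evaluate(clf, eval_id, config))
            arm_out["ood"].append(_evaluate(clf, eval_ood, config))
        report["arms"][arm] = {
            split: _aggregate(arm_out[split]) for split in ("in_distribution", "ood")
        }
    if out_dir is not None:
        _write_report(report, config, out_dir)
    return report


def _aggregate(per_seed: list) -> dict:
    scalar_keys = [
        k for k in per_seed[0] if isinstance(per_seed[0][k], (int, float))
    ]
    out = {"per_seed": per_seed}
    for key in scalar_keys:
        vals = [r[key] for r in per_seed if key in r]
        out[key] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
    return out


def _write_report(report: dict, config: ExperimentConfig, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    (out_dir / "config.yaml").write_text(dump_config(config))
    rows = []
    for arm, splits in report["arms"].items():
        for split, agg in splits.items():
            for i, seed_metrics in enumerate(agg["per_seed"]):
                for metric, value in seed_metrics.items():
                    if isinstance(value, (int, float)):
                        rows.append(
                            {
                                "arm": arm,
                                "split": split,
                                "seed_index": i,
                                "metric": metric,
                                "value": value,
                            }
                        )
    pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)
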