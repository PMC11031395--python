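"""Seeded toy image cohorts with controllable label, attribute and domain structure.

The generator emulates the statistical structure of multi-site medical imaging
collections without any clinical data: a diagnostic label is planted in the
geometry of a centred blob (its radius), a sensitive attribute is planted in the
hue of a corner marker (a label-irrelevant cue whose visibility is controlled by
``spurious_strength``), and an acquisition domain (hospital / scanner / stain)
is planted as a global additive colour cast.  Because each factor enters the
image through an independent mechanism, each can be ablated on its own, and the
Bayes-optimal labelling rule is known exactly (``Cohort.planted_rule``).

All randomness flows through :class:`numpy.random.Generator` objects seeded
from the config, so cohorts are pure functions of ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image as PILImage
from scipy import ndimage

__all__ = [
    "AttributeSpec",
    "CohortConfig",
    "Example",
    "PlantedRule",
    "Cohort",
    "generate_cohort",
    "render_example_image",
    "skew_dataset",
    "strip_labels",
    "bucketize_attribute",
    "write_dataset",
    "read_dataset",
    "DEFAULT_AGE_EDGES",
]

#: Default discretisation edges for an age-style continuous attribute
#: (minor / young adult / middle-aged / senior).  Configurable everywhere.
DEFAULT_AGE_EDGES = (18.0, 40.0, 65.0)

# Corner anchors for attribute hue markers: (row, col) of the marker's
# top-left pixel as a fraction of image size.  One corner per attribute.
_CORNERS = ((0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0))


@dataclass(frozen=True)
class AttributeSpec:
    """A categorical sensitive attribute with a label-conditional distribution.

    ``table`` has one row per label, one column per attribute value; row ``y``
    is p(a | y).  A skewed table plants a label-attribute correlation that a
    classifier can exploit through the attribute's image cue.
    """

    name: str
    values: tuple
    table: tuple  # (n_labels, n_values) nested tuples, rows sum to 1

    def table_array(self) -> np.ndarray:
        return np.asarray(self.table, dtype=float)


@dataclass(frozen=True)
class CohortConfig:
    n_examples: int
    image_size: int = 16
    n_labels: int = 2
    label_prevalence: tuple = (0.5, 0.5)
    attributes: tuple = ()  # tuple of AttributeSpec
    n_domains: int = 1
    domain_effect: tuple = ()  # (n_domains, 3) additive RGB casts in [0,1] units
    spurious_strength: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.label_prevalence, dtype=float)
        if len(p) != self.n_labels:
            raise ValueError(
                f"label_prevalence has length {len(p)} but n_labels={self.n_labels}"
            )
        if not np.isclose(p.sum(), 1.0):
            raise ValueError(f"label_prevalence must sum to 1, got {p.sum()!r}")
        if np.any(p < 0):
            raise ValueError("label_prevalence must be non-negative")
        if not (0.0 <= self.spurious_strength <= 1.0):
            raise ValueError(
                f"spurious_strength must lie in [0, 1], got {self.spurious_strength}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_examples < 0:
            raise ValueError("n_examples must be >= 0")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        for spec in self.attributes:
            t = spec.table_array()
            if t.shape != (self.n_labels, len(spec.values)):
                raise ValueError(
                    f"attribute {spec.name!r}: table shape {t.shape} does not match "
                    f"(n_labels, n_values)=({self.n_labels}, {len(spec.values)})"
                )
            if not np.allclose(t.sum(axis=1), 1.0):
                raise ValueError(
                    f"attribute {spec.name!r}: each row of p(a|y) must sum to 1"
                )
            if np.any(t < 0):
                raise ValueError(f"attribute {spec.name!r}: p(a|y) must be non-negative")
        if len(self.attributes) > len(_CORNERS):
            raise ValueError(f"at most {len(_CORNERS)} attributes supported")
        de = self.domain_casts()
        if de.shape != (self.n_domains, 3):
            raise ValueError(
                f"domain_effect must have shape ({self.n_domains}, 3), got {de.shape}"
            )

    def domain_casts(self) -> np.ndarray:
        """Per-domain additive RGB cast; zeros when unspecified."""
        if len(self.domain_effect) == 0:
            return np.zeros((self.n_domains, 3))
        return np.asarray(self.domain_effect, dtype=float)


def default_domain_casts(n_domains: int, magnitude: float = 0.08) -> tuple:
    """Evenly-rotated RGB casts of a given magnitude, one per domain.

    Emulates per-site acquisition shift (staining protocol, scanner white
    balance): domain d receives an additive cast of norm ``magnitude`` whose
    direction rotates around the colour wheel.
    """
    angles = 2 * np.pi * np.arange(n_domains) / max(n_domains, 1)
    casts = magnitude * np.stack(
        [np.cos(angles), np.cos(angles + 2 * np.pi / 3), np.cos(angles + 4 * np.pi / 3)],
        axis=1,
    )
    return tuple(tuple(float(v) for v in row) for row in casts)


@dataclass
class Example:
    """One image with optional label information — the atom of every dataset."""

    image: np.ndarray  # H x W x 3 float in [0, 1]
    label: int | None
    soft_label: np.ndarray | None
    attributes: dict
    domain: int
    labeled: bool
    synthetic: bool = False
    example_id: str = ""

    def __post_init__(self):
        if not self.labeled and (self.label is not None or self.soft_label is not None):
            raise ValueError("unlabeled example must not carry a label or soft label")
        if self.soft_label is not None:
            s = np.asarray(self.soft_label, dtype=float)
            if np.any(s < 0) or not np.isclose(s.sum(), 1.0, atol=1e-9):
                raise ValueError("soft_label must be non-negative and sum to 1")


# Blob radii span this fraction of the half-image; label y gets the y-th radius.
_R_MIN_FRAC, _R_MAX_FRAC = 0.18, 0.42
_BLOB_COLOR = np.array([0.78, 0.42, 0.46])  # stained-tissue foreground
_BACKGROUND = 0.40
_MARKER_FRAC = 0.25  # corner marker side as a fraction of image size


def _label_radii(image_size: int, n_labels: int) -> np.ndarray:
    lo, hi = _R_MIN_FRAC * image_size, _R_MAX_FRAC * image_size
    if n_labels == 1:
        return np.array([(lo + hi) / 2])
    return lo + (hi - lo) * np.arange(n_labels) / (n_labels - 1)


def _attribute_hue(value_index: int, n_values: int) -> np.ndarray:
    """Distinct saturated RGB colour per attribute value (evenly spaced hue)."""
    h = value_index / max(n_values, 1)
    # minimal hsv->rgb for s=1, v=1
    i = int(h * 6) % 6
    f = h * 6 - int(h * 6)
    table = [(1, f, 0), (1 - f, 1, 0), (0, 1, f), (0, 1 - f, 1), (f, 0, 1), (1, 0, 1 - f)]
    return np.asarray(table[i], dtype=float)


@dataclass(frozen=True)
class PlantedRule:
    """The label-generating image feature, for oracle evaluation.

    The label is encoded as the radius of the centred blob; prediction
    correlates the image against zero-mean disk templates (one per label) so
    that additive domain casts cancel exactly.
    """

    image_size: int
    radii: tuple

    def templates(self) -> np.ndarray:
        size = self.image_size
        yy, xx = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2.0
        dist = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
        temps = []
        for r in self.radii:
            mask = (dist <= r).astype(float)
            temps.append(mask - mask.mean())
        return np.stack(temps)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Oracle labels for a batch of H x W x 3 images."""
        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        gray = images.mean(axis=3)
        temps = self.templates()  # (L, H, W)
        # redness of the blob relative to background makes the red channel the
        # most contrastive; use gray minus background for robustness instead
        signal = gray - gray.mean(axis=(1, 2), keepdims=True)
        scores = np.einsum("nhw,lhw->nl", signal, temps)
        # blob is darker in green/blue than background -> correlate on negative
        # contrast when the blob darkens the mean; pick by absolute match
        return np.argmax(np.abs(scores), axis=1)


def render_example_image(
    config: CohortConfig,
    label: int,
    attribute_indices: Sequence[int],
    domain: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one image from the planted parametric rule.

    Layers, in order: smooth background texture, centred label-radius blob,
    one hue marker per attribute (scaled by ``spurious_strength``), additive
    domain cast, i.i.d. pixel noise; clipped to [0, 1].
    """
    size = config.image_size
    texture = rng.uniform(-1.0, 1.0, size=(size, size))
    texture = ndimage.gaussian_filter(texture, sigma=2.0, mode="wrap")
    img = np.empty((size, size, 3))
    img[:] = (_BACKGROUND + 0.06 * texture)[..., None]

    radii = _label_radii(size, config.n_labels)
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    dist = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    # soft edge ~0.7px wide keeps the radius information sub-pixel accurate
    mask = 1.0 / (1.0 + np.exp((dist - radii[label]) / 0.35))
    img = img * (1 - mask[..., None]) + mask[..., None] * _BLOB_COLOR

    m = max(2, int(round(_MARKER_FRAC * size)))
    s = config.spurious_strength
    for k, (spec, vi) in enumerate(zip(config.attributes, attribute_indices)):
        fr, fc = _CORNERS[k]
        r0 = int(round(fr * (size - m)))
        c0 = int(round(fc * (size - m)))
        color = _attribute_hue(vi, len(spec.values))
        patch = img[r0 : r0 + m, c0 : c0 + m]
        img[r0 : r0 + m, c0 : c0 + m] = (1 - s) * patch + s * color

    img = img + config.domain_casts()[domain]
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


@dataclass
class Cohort:
    examples: list
    config: CohortConfig
    planted_rule: PlantedRule

    def __len__(self) -> int:
        return len(self.examples)

    def labeled_examples(self) -> list:
        return [e for e in self.examples if e.labeled]

    def images(self) -> np.ndarray:
        return np.stack([e.image for e in self.examples])

    def labels(self) -> np.ndarray:
        return np.array(
            [e.label if e.label is not None else -1 for e in self.examples], dtype=int
        )

    def attribute_values(self, name: str) -> np.ndarray:
        return np.array([e.attributes[name] for e in self.examples])

    def domains(self) -> np.ndarray:
        return np.array([e.domain for e in self.examples], dtype=int)

    def subset(self, indices: Sequence[int]) -> "Cohort":
        return Cohort(
            examples=[self.examples[i] for i in indices],
            config=self.config,
            planted_rule=self.planted_rule,
        )

    def metadata_frame(self) -> pd.DataFrame:
        """Deterministic metadata table (no pixel data)."""
        rows = []
        for e in self.examples:
            row = {
                "image": f"images/{e.example_id}.png",
                "label": "" if e.label is None else int(e.label),
                "soft_label": ""
                if e.soft_label is None
                else ";".join(f"{v:.9f}" for v in e.soft_label),
                "domain": int(e.domain),
                "labeled": bool(e.labeled),
                "synthetic": bool(e.synthetic),
            }
            for name, value in e.attributes.items():
                row[name] = value
            rows.append(row)
        return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a cohort from the planted generative process, seeded by the config.

    Per example: label ~ label_prevalence; each attribute value ~ p(a | y);
    domain ~ uniform over domains; image rendered by the fixed parametric rule.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_examples
    labels = rng.choice(config.n_labels, size=n, p=np.asarray(config.label_prevalence))
    domains = rng.integers(0, config.n_domains, size=n)
    attr_indices = np.zeros((n, len(config.attributes)), dtype=int)
    for j, spec in enumerate(config.attributes):
        table = spec.table_array()
        u = rng.random(n)
        cdf = np.cumsum(table, axis=1)
        attr_indices[:, j] = (u[:, None] > cdf[labels]).sum(axis=1)

    examples = []
    for i in range(n):
        img = render_example_image(
            config, int(labels[i]), attr_indices[i], int(domains[i]), rng
        )
        attrs = {
            spec.name: spec.values[attr_indices[i, j]]
            for j, spec in enumerate(config.attributes)
        }
        examples.append(
            Example(
                image=img,
                label=int(labels[i]),
                soft_label=None,
                attributes=attrs,
                domain=int(domains[i]),
                labeled=True,
                example_id=f"{i:06d}",
            )
        )
    rule = PlantedRule(
        image_size=config.image_size,
        radii=tuple(float(r) for r in _label_radii(config.image_size, config.n_labels)),
    )
    return Cohort(examples=examples, config=config, planted_rule=rule)


def skew_dataset(cohort: Cohort, attribute_name: str, cap: int, seed: int) -> Cohort:
    """Cap every minority value of an attribute at ``cap`` labeled examples.

    The most represented value (by labeled count) and all unlabeled examples
    are untouched; removal within a capped subgroup is uniform at random,
    seeded.  This induces controlled subgroup under-representation.
    """
    if cap < 0:
        raise ValueError("cap must be >= 0")
    labeled = [e for e in cohort.examples if e.labeled]
    if labeled and attribute_name not in labeled[0].attributes:
        raise KeyError(f"unknown attribute {attribute_name!r}")
    counts: dict = {}
    for e in labeled:
        counts[e.attributes[attribute_name]] = counts.get(e.attributes[attribute_name], 0) + 1
    if not counts:
        return Cohort(list(cohort.examples), cohort.config, cohort.planted_rule)
    majority = max(sorted(counts, key=str), key=lambda v: counts[v])

    rng = np.random.default_rng(seed)
    keep: set = set()
    by_value: dict = {}
    for i, e in enumerate(cohort.examples):
        if not e.labeled:
            keep.add(i)
            continue
        v = e.attributes[attribute_name]
        if v == majority:
            keep.add(i)
        else:
            by_value.setdefault(v, []).append(i)
    for v in sorted(by_value, key=str):
        idx = by_value[v]
        if len(idx) <= cap:
            keep.update(idx)
        else:
            keep.update(rng.choice(idx, size=cap, replace=False).tolist())
    kept = sorted(keep)
    return cohort.subset(kept)


def strip_labels(cohort: Cohort, fraction: float, keep_domain: bool, seed: int) -> Cohort:
    """Remove labels from a seeded random fraction of examples.

    Implemented as a seeded permutation split so the unlabeled count is exactly
    ``round(fraction * n)``.  Emulates unlabeled pools that carry acquisition
    metadata (the domain id) but no diagnosis when ``keep_domain`` is true.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    n = len(cohort.examples)
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    strip_idx = set(rng.permutation(n)[:k].tolist())
    out = []
    for i, e in enumerate(cohort.examples):
        if i in strip_idx:
            out.append(
                Example(
                    image=e.image,
                    label=None,
                    soft_label=None,
                    attributes=dict(e.attributes),
                    domain=e.domain if keep_domain else -1,
                    labeled=False,
                    synthetic=e.synthetic,
                    example_id=e.example_id,
                )
            )
        else:
            out.append(e)
    return Cohort(out, cohort.config, cohort.planted_rule)


def bucketize_attribute(values: Sequence[float], edges: Sequence[float]) -> list:
    """Discretise a continuous attribute into half-open buckets [e_i, e_{i+1}).

    Values below the first edge map to bucket 0; values at or above the last
    edge map to the last bucket.
    """
    edges = list(edges)
    if not edges:
        raise ValueError("edges must be non-empty")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    return np.searchsorted(np.asarray(edges), np.asarray(values, dtype=float), side="right").tolist()


_BASE_COLUMNS = ["image", "label", "soft_label", "domain", "labeled", "synthetic"]


def write_dataset(cohort: Cohort, path) -> None:
    """Write a cohort as PNG images plus a metadata CSV (plus config JSON)."""
    path = Path(path)
    (path / "images").mkdir(parents=True, exist_ok=True)
    for e in cohort.examples:
        arr = np.clip(np.round(e.image * 255), 0, 255).astype(np.uint8)
        PILImage.fromarray(arr).save(path / "images" / f"{e.example_id}.png")
    cohort.metadata_frame().to_csv(path / "metadata.csv", index=False)
    cfg = dataclasses.asdict(cohort.config)
    cfg["attributes"] = [dataclasses.asdict(a) for a in cohort.config.attributes]
    meta = {"config": cfg, "planted_rule": dataclasses.asdict(cohort.planted_rule)}
    (path / "cohort.json").write_text(json.dumps(meta, indent=1, default=list))


def _parse_config(cfg: dict) -> CohortConfig:
    attrs = tuple(
        AttributeSpec(
            name=a["name"],
            values=tuple(a["values"]),
            table=tuple(tuple(row) for row in a["table"]),
        )
        for a in cfg.pop("attributes", [])
    )
    cfg["label_prevalence"] = tuple(cfg["label_prevalence"])
    cfg["domain_effect"] = tuple(tuple(r) for r in cfg.get("domain_effect", ()))
    return CohortConfig(attributes=attrs, **cfg)


def read_dataset(path) -> Cohort:
    """Read a cohort written by :func:`write_dataset`, validating the metadata."""
    path = Path(path)
    meta = json.loads((path / "cohort.json").read_text())
    config = _parse_config(meta["config"])
    rule = PlantedRule(
        image_size=meta["planted_rule"]["image_size"],
        radii=tuple(meta["planted_rule"]["radii"]),
    )
    df = pd.read_csv(path / "metadata.csv", dtype={"label": "string", "soft_label": "string"})
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata.csv missing required columns: {missing}")
    attr_names = [c for c in df.columns if c not in _BASE_COLUMNS]
    examples = []
    for i, row in df.iterrows():
        labeled = bool(row["labeled"])
        raw_label = row["label"]
        has_label = isinstance(raw_label, str) and raw_label.strip() != ""
        if labeled and not has_label and (
            not isinstance(row["soft_label"], str) or row["soft_label"].strip() == ""
        ):
            raise ValueError(f"metadata.csv row {i}: labeled=true but no label or soft_label")
        if not labeled and has_label:
            raise ValueError(f"metadata.csv row {i}: labeled=false but label present")
        img_path = path / str(row["image"])
        if not img_path.exists():
            raise ValueError(f"metadata.csv row {i}: missing image file {row['image']}")
        img = np.asarray(PILImage.open(img_path), dtype=np.float32) / 255.0
        soft = None
        if isinstance(row["soft_label"], str) and row["soft_label"].strip():
            soft = np.array([float(v) for v in row["soft_label"].split(";")])
        examples.append(
            Example(
                image=img,
                label=int(raw_label) if (labeled and has_label) else None,
                soft_label=soft if labeled else None,
                attributes={a: row[a] for a in attr_names},
                domain=int(row["domain"]),
                labeled=labeled,
                synthetic=bool(row["synthetic"]),
                example_id=Path(str(row["image"])).stem,
            )
        )
    return Cohort(examples=examples, config=config, planted_rule=rule)
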