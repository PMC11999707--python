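"""End-to-end benchmarking of attribution methods on planted-signal data.

A run generates (or loads) patched images with known ground truth, scores
them with every configured attribution method, evaluates each ranking
with the insertion/deletion metrics, aggregates per patch image and per
slide, compares method populations with Welch's t-test, and renders
red/blue heatmap overlays.  Everything is deterministic given the run
seed; a method that fails on an image is recorded as a failed cell and
the run continues.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import CapabilityError, ConfigError, InputError, SizeError, SolverError
from .integrated_gradients import IGConfig, integrated_gradients
from .metrics import (
    AttributionMap,
    aggregate,
    deletion_curve,
    insertion_curve,
    rank_patches,
    top_k_precision,
    welch_t_matrix,
)
from .models import ClassifierAdapter, PatchedImage
from .rise import RiseConfig, rise_attribution
from .rollout import RolloutConfig, rollout_attribution
from .shapley import (
    ExplainerModel,
    ExplainerTrainConfig,
    exact_shapley,
    make_image_game,
    random_additive_games,
    regression_shapley,
    singleton_features,
    train_explainer,
)
from .synthetic import (
    TUMOR,
    GroundTruth,
    SyntheticSlideSpec,
    generate_pseudo_slide,
    make_tumor_signal_scorer,
)

__all__ = [
    "RunConfig",
    "BenchmarkReport",
    "run_benchmark",
    "render_heatmap",
    "METHODS",
    "attribute_image",
]


# ---------------------------------------------------------------------------
# method registry
# ---------------------------------------------------------------------------


def _m_rollout(adapter, image, class_index, seed, opts):
    stack = adapter.attention_maps(image)
    return rollout_attribution(stack, RolloutConfig(residual=False))


def _m_rollout_res(adapter, image, class_index, seed, opts):
    stack = adapter.attention_maps(image)
    m = rollout_attribution(stack, RolloutConfig(residual=True, renormalize=True))
    return AttributionMap(m.scores, method="rollout-res")


def _m_ig(adapter, image, class_index, seed, opts):
    cfg = IGConfig(steps=opts.get("ig_steps", 64))
    _, amap = integrated_gradients(adapter, image, class_index, cfg)
    return amap


def _m_rise(scheme):
    def run(adapter, image, class_index, seed, opts):
        cfg = RiseConfig(
            n_masks=opts.get("rise_n_masks", 4000),
            scheme=scheme,
            p=opts.get("rise_p", 0.5),
            masks_per_chunk=opts.get("masks_per_chunk", 512),
            fill=opts.get("fill", 0.0),
        )
        return rise_attribution(adapter, image, class_index, cfg, seed=seed)

    return run


def _m_shapley_exact(adapter, image, class_index, seed, opts):
    game = make_image_game(adapter, image, class_index, fill=opts.get("fill", 0.0))
    return exact_shapley(game).as_map(class_index=class_index)


def _m_shapley_regression(adapter, image, class_index, seed, opts):
    game = make_image_game(adapter, image, class_index, fill=opts.get("fill", 0.0))
    res = regression_shapley(
        game, n_masks=opts.get("shapley_n_masks", 2048), seed=seed
    )
    return res.as_map(class_index=class_index)


def _m_shapley_explainer(adapter, image, class_index, seed, opts):
    game = make_image_game(adapter, image, class_index, fill=opts.get("fill", 0.0))
    explainer = opts.get("explainer")
    if explainer is None:
        # train a fresh toy explainer on random additive games of matching d
        explainer = ExplainerModel(game.d, seed=seed)
        train_games = random_additive_games(24, game.d, seed=seed)
        explainer, _ = train_explainer(
            train_games,
            explainer,
            config=ExplainerTrainConfig(epochs=30, seed=seed),
        )
        opts["explainer"] = explainer  # reuse across images of a run
    phi = explainer.forward(singleton_features(game), game.grand_value())
    return AttributionMap(phi, method="shapley-explainer", class_index=class_index)


def _m_random(adapter, image, class_index, seed, opts):
    rng = np.random.default_rng(seed)
    return AttributionMap(rng.random(image.d), method="random")


METHODS = {
    "rollout": _m_rollout,
    "rollout-res": _m_rollout_res,
    "ig": _m_ig,
    "rise-binomial": _m_rise("binomial"),
    "rise-uniform": _m_rise("uniform_cardinality"),
    "shapley-exact": _m_shapley_exact,
    "shapley-regression": _m_shapley_regression,
    "shapley-explainer": _m_shapley_explainer,
    "random": _m_random,
}


def attribute_image(
    method: str,
    adapter: ClassifierAdapter,
    image: PatchedImage,
    class_index: int = 1,
    seed: int = 0,
    options: dict | None = None,
) -> AttributionMap:
    """Run a registered attribution method by name."""
    if method not in METHODS:
        raise ConfigError(f"unknown method {method!r}; have {sorted(METHODS)}")
    amap = METHODS[method](adapter, image, class_index, seed, options or {})
    return AttributionMap(
        amap.scores, method=method, class_index=class_index, meta=dict(amap.meta)
    )


# ---------------------------------------------------------------------------
# run configuration and report
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a synthetic benchmark run (YAML-serialisable)."""

    grid: tuple[int, int] = (3, 4)  # d = 12 keeps exact Shapley inside its guard
    patch_size: int = 16
    n_tumor: int = 3
    n_background: int = 5
    noise_scale: float = 0.0
    n_slides: int = 1
    images_per_slide: int = 1
    methods: tuple[str, ...] = ("shapley-exact", "rise-binomial", "rollout", "ig", "random")
    metrics: tuple[str, ...] = ("insertion", "deletion")
    method_options: dict = field(default_factory=dict)
    random_repeats: int = 20
    class_index: int = 1
    fill: float = 0.0
    seed: int = 0
    output_dir: str | None = None
    render: bool = False
    render_alpha: float = 0.5

    def __post_init__(self) -> None:
        if not self.methods or not self.metrics:
            raise ConfigError("need at least one method and one metric")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ConfigError(f"unknown methods {sorted(unknown)}")
        bad = set(self.metrics) - {"insertion", "deletion"}
        if bad:
            raise ConfigError(f"unknown metrics {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        for key in ("grid", "methods", "metrics"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class BenchmarkReport:
    scores: pd.DataFrame  # image_id, slide_id, method, patch, score, label
    aucs: pd.DataFrame  # image_id, slide_id, method, metric, auc
    summary: pd.DataFrame  # method, metric, per_patch, per_slide
    precision: pd.DataFrame  # image_id, method, top_k_precision
    welch: dict[str, pd.DataFrame]  # metric -> p-value matrix (None-capable)
    failures: pd.DataFrame  # image_id, method, reason
    provenance: dict

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = lambda df: df.to_csv(index=False, float_format="%.12g")
        (out / "scores.csv").write_text(fmt(self.scores))
        (out / "aucs.csv").write_text(fmt(self.aucs))
        (out / "summary.csv").write_text(fmt(self.summary))
        (out / "precision.csv").write_text(fmt(self.precision))
        (out / "failures.csv").write_text(fmt(self.failures))
        payload = {
            "provenance": self.provenance,
            "summary": self.summary.to_dict(orient="records"),
            "precision": self.precision.to_dict(orient="records"),
            "welch": {
                metric: json.loads(mat.to_json(orient="split"))
                for metric, mat in self.welch.items()
            },
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        return out


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------


def _generate_inputs(config: RunConfig):
    """One pseudo-slide dataset per (slide, image) cell, each with its own
    seeded tumor placement."""
    inputs = []
    d = config.grid[0] * config.grid[1]
    for s in range(config.n_slides):
        for j in range(config.images_per_slide):
            sub = config.seed * 10_000 + s * 100 + j
            rng = np.random.default_rng(sub)
            cells = rng.permutation(d)
            spec = SyntheticSlideSpec(
                grid=config.grid,
                patch_size=config.patch_size,
                tumor_patches=frozenset(int(i) for i in cells[: config.n_tumor]),
                background_patches=frozenset(
                    int(i) for i in cells[config.n_tumor : config.n_tumor + config.n_background]
                ),
                noise_scale=config.noise_scale,
                seed=sub,
            )
            image, truth = generate_pseudo_slide(spec)
            inputs.append((f"slide_{s}", f"slide_{s}_img_{j}", image, truth))
    return inputs


def run_benchmark(config: RunConfig) -> BenchmarkReport:
    """Execute the full synthetic protocol and (optionally) write artifacts."""
    inputs = _generate_inputs(config)
    if not inputs:
        raise InputError("run produced no input images")
    score_rows, auc_rows, prec_rows, fail_rows = [], [], [], []
    shared_opts = dict(config.method_options)
    shared_opts.setdefault("fill", config.fill)
    for slide_id, image_id, image, truth in inputs:
        adapter = make_tumor_signal_scorer(truth)
        tumor_idx = truth.indices(TUMOR)
        for method in config.methods:
            seed = config.seed * 1_000 + hash_seed(image_id, method)
            try:
                amap = attribute_image(
                    method, adapter, image, config.class_index, seed, shared_opts
                )
            except (CapabilityError, InputError, ConfigError, SizeError, SolverError) as exc:
                fail_rows.append(
                    {"image_id": image_id, "method": method, "reason": str(exc)}
                )
                continue
            for patch, score in enumerate(amap.scores):
                score_rows.append(
                    {
                        "image_id": image_id,
                        "slide_id": slide_id,
                        "method": method,
                        "patch": patch,
                        "score": score,
                        "label": truth.patch_labels[patch],
                    }
                )
            if len(tumor_idx):
                prec_rows.append(
                    {
                        "image_id": image_id,
                        "method": method,
                        "top_k_precision": top_k_precision(amap.scores, tumor_idx),
                    }
                )
            ranking = rank_patches(amap)
            for metric in config.metrics:
                curve_fn = insertion_curve if metric == "insertion" else deletion_curve
                curve = curve_fn(
                    adapter, image, config.class_index, ranking, config.fill
                )
                auc_rows.append(
                    {
                        "image_id": image_id,
                        "slide_id": slide_id,
                        "method": method,
                        "metric": metric,
                        "auc": curve.auc,
                    }
                )
    aucs = pd.DataFrame(auc_rows, columns=["image_id", "slide_id", "method", "metric", "auc"])
    summary_rows = []
    for (method, metric), grp in aucs.groupby(["method", "metric"], sort=True):
        pairs = list(zip(grp["slide_id"], grp["auc"]))
        summary_rows.append(
            {
                "method": method,
                "metric": metric,
                "per_patch": aggregate(pairs, "per_patch"),
                "per_slide": aggregate(pairs, "per_slide"),
            }
        )
    summary = pd.DataFrame(
        summary_rows, columns=["method", "metric", "per_patch", "per_slide"]
    )
    welch: dict[str, pd.DataFrame] = {}
    for metric in config.metrics:
        pops = {
            method: grp["auc"].to_numpy()
            for method, grp in aucs[aucs["metric"] == metric].groupby("method")
            if grp.shape[0] >= 2
        }
        if len(pops) >= 2:
            welch[metric] = welch_t_matrix(pops)
    report = BenchmarkReport(
        scores=pd.DataFrame(
            score_rows,
            columns=["image_id", "slide_id", "method", "patch", "score", "label"],
        ),
        aucs=aucs,
        summary=summary,
        precision=pd.DataFrame(
            prec_rows, columns=["image_id", "method", "top_k_precision"]
        ),
        welch=welch,
        failures=pd.DataFrame(fail_rows, columns=["image_id", "method", "reason"]),
        provenance={
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()
                if k not in ("method_options", "output_dir")
            },
            "config_hash": hashlib.sha256(
                json.dumps(
                    {
                        k: str(v)
                        for k, v in asdict(config).items()
                        if k != "output_dir"
                    },
                    sort_keys=True,
                ).encode()
            ).hexdigest()[:16],
            "seed": config.seed,
            "version": __version__,
        },
    )
    if config.output_dir:
        out = report.write(config.output_dir)
        if config.render:
            _render_all(inputs, config, out)
    return report


def hash_seed(*parts: str) -> int:
    """Stable small seed offset from string identifiers."""
    digest = hashlib.sha256("|".join(parts).encode()).digest()
    return int.from_bytes(digest[:2], "little")


def _render_all(inputs, config: RunConfig, out: Path) -> None:
    from PIL import Image as PILImage

    for slide_id, image_id, image, truth in inputs:
        adapter = make_tumor_signal_scorer(truth)
        for method in config.methods:
            seed = config.seed * 1_000 + hash_seed(image_id, method)
            try:
                amap = attribute_image(
                    method, adapter, image, config.class_index, seed,
                    dict(config.method_options, fill=config.fill),
                )
            except (CapabilityError, InputError, ConfigError, SizeError, SolverError):
                continue
            overlay = render_heatmap(image, amap, alpha=config.render_alpha)
            arr = (np.clip(overlay, 0, 1) * 255).round().astype(np.uint8)
            PILImage.fromarray(arr).save(out / f"{image_id}_{method}_overlay.png")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_heatmap(
    image: PatchedImage, amap: AttributionMap, alpha: float = 0.5
) -> np.ndarray:
    """Alpha-blend a diverging blue-to-red patch heatmap over the image.

    Scores are min-max normalised per image (red = most important); a
    constant map renders at the colormap midpoint.  ``alpha = 0`` returns
    the original pixels unchanged.
    """
    from matplotlib import colormaps

    if amap.d != image.d:
        raise InputError("attribution length does not match the image grid")
    if not 0.0 <= alpha <= 1.0:
        raise InputError("alpha must lie in [0, 1]")
    s = amap.scores
    span = s.max() - s.min()
    norm = np.full_like(s, 0.5) if span == 0 else (s - s.min()) / span
    rows, cols = image.grid
    grid = norm.reshape(rows, cols)
    colors = colormaps["bwr"](grid)[..., :3]  # blue -> white -> red
    pixel_colors = np.kron(colors, np.ones((image.patch_size, image.patch_size, 1)))
    return (1.0 - alpha) * image.pixels + alpha * pixel_colors
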