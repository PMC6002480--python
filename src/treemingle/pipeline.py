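"""One-command orchestration of the full mingling analysis.

Two reports mirror the two halves of the analysis:

* :func:`run_mingling_report` — per-tree mingling indices, pairwise
  dbh-by-mingling-level rank tests with significance letters, and the
  bivariate dbh x mingling density.
* :func:`run_curve_report` — per-size-class mark mingling curves and the
  pairwise size-class difference curves, each with Monte-Carlo null-model
  envelopes.

All numeric content is written as CSV (plots are optional artifacts) and a
JSON manifest records every output with the config digest and seed, so
reruns with identical config and seed reproduce the tables byte for byte.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .curves import RGrid, class_mingling_curves, expected_mingling
from .mingling import bivariate_density, dbh_by_mingling_test, mingling_summary
from .nullmodels import EnvelopeResult, envelope
from .pattern import (
    MarkedPointPattern,
    SizeClassScheme,
    TWO_CLASS_SCHEME,
    Window,
    load_census,
)
from .simulate import (
    CommunityConfig,
    DependentMarkingConfig,
    rare_large_community,
    shared_size_community,
    simulate_community,
    simulate_dependent_marking,
)

__all__ = ["RunConfig", "run_mingling_report", "run_curve_report", "resolve_pattern"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a pipeline run.

    ``source`` selects the input: a census CSV path, or one of the
    generator names ``"dependent-marking"``, ``"community-shared-size"``,
    ``"community-rare-large"``.
    """

    source: str = "dependent-marking"
    window: Window = field(default_factory=lambda: Window(0, 0, 100, 100))
    k: int = 4
    scheme: SizeClassScheme = field(default_factory=SizeClassScheme)
    grid: RGrid = field(default_factory=lambda: RGrid(r_max=25.0, step=0.25))
    null_kind: str = "homogeneous"
    nsim: int = 199
    seed: int = 0
    out_dir: Path = Path("treemingle-out")
    plots: bool = True
    intensity_bandwidth: float = 20.0
    intensity_grid_step: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs: dict = {}
        for key in (
            "source", "k", "null_kind", "nsim", "seed", "plots",
            "intensity_bandwidth", "intensity_grid_step",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "window" in raw:
            kwargs["window"] = Window(**raw["window"])
        if "grid" in raw:
            kwargs["grid"] = RGrid(**raw["grid"])
        if "scheme" in raw:
            s = raw["scheme"]
            kwargs["scheme"] = SizeClassScheme(
                labels=tuple(s["labels"]),
                breaks=tuple(s["breaks"]),
                boundary_belongs=tuple(s["boundary_belongs"]),
            )
        if "out_dir" in raw:
            kwargs["out_dir"] = Path(raw["out_dir"])
        return cls(**kwargs)

    def digest(self) -> str:
        def default(o):
            if isinstance(o, Path):
                return str(o)
            return asdict(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def resolve_pattern(config: RunConfig) -> MarkedPointPattern:
    """Load or generate the input pattern named by ``config.source``."""
    if config.source == "dependent-marking":
        return simulate_dependent_marking(
            DependentMarkingConfig(window=config.window), seed=config.seed
        )
    if config.source == "community-shared-size":
        return simulate_community(shared_size_community(), seed=config.seed)
    if config.source == "community-rare-large":
        return simulate_community(rare_large_community(), seed=config.seed)
    return load_census(config.source, config.window)


class _Manifest:
    def __init__(self, config: RunConfig):
        self.config = config
        self.entries: list[dict] = []
        self.t0 = time.perf_counter()

    def add(self, path: Path, kind: str) -> None:
        self.entries.append(
            {
                "path": path.name,
                "kind": kind,
                "elapsed_s": round(time.perf_counter() - self.t0, 3),
            }
        )

    def write(self, out_dir: Path) -> Path:
        payload = {
            "config_digest": self.config.digest(),
            "seed": self.config.seed,
            "source": str(self.config.source),
            "outputs": self.entries,
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(payload, indent=2))
        return path


def run_mingling_report(config: RunConfig) -> dict[str, Path]:
    """Nearest-neighbour mingling analysis: index table, rank tests, density."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    pattern = resolve_pattern(config)
    logger.info(
        "mingling report: n=%d trees, %d species, seed=%d",
        pattern.n, len(pattern.species_counts()), config.seed,
    )
    summary = mingling_summary(pattern, k=config.k)
    outputs: dict[str, Path] = {}

    per_tree = out_dir / "mingling_per_tree.csv"
    summary.to_dataframe(pattern).to_csv(per_tree, index=False)
    manifest.add(per_tree, "per-tree mingling")
    outputs["per_tree"] = per_tree

    occupied = [lab for lab, c in summary.level_counts.items() if c >= 2]
    if len(occupied) >= 2:
        tests = dbh_by_mingling_test(pattern, summary)
        table = tests.table.copy()
        table["letters_a"] = table["level_a"].map(tests.letters)
        table["letters_b"] = table["level_b"].map(tests.letters)
        tests_path = out_dir / "dbh_by_mingling_tests.csv"
        table.to_csv(tests_path, index=False)
        manifest.add(tests_path, "pairwise rank tests")
        outputs["tests"] = tests_path
    else:
        logger.warning(
            "only %d occupied mingling level(s); rank tests skipped", len(occupied)
        )

    dens = bivariate_density(pattern, summary)
    dens_path = out_dir / "bivariate_density.csv"
    dens.to_dataframe().to_csv(dens_path, index=False)
    manifest.add(dens_path, "bivariate density")
    outputs["density"] = dens_path

    if config.plots:
        outputs["plots"] = _plot_mingling(pattern, summary, dens, out_dir, manifest)
    outputs["manifest"] = manifest.write(out_dir)
    return outputs


def _delta_pairs(labels: tuple[str, ...]) -> list[tuple[str, str]]:
    # larger class minus smaller class, for every ordered pair
    return [
        (hi, lo)
        for lo, hi in itertools.combinations(labels, 2)
    ]


def stacked_class_statistic(
    grid: RGrid,
    scheme: SizeClassScheme,
    classes: tuple[str, ...],
    deltas: list[tuple[str, str]],
):
    """Statistic returning all class curves and delta curves concatenated.

    Used inside :func:`treemingle.nullmodels.envelope` so a single pass over
    the pair matrix per replicate yields every curve at once.
    """

    def stat(pattern: MarkedPointPattern) -> np.ndarray:
        curves = class_mingling_curves(pattern, grid, scheme, classes)
        parts = [curves[c] for c in classes]
        parts += [curves[hi] - curves[lo] for hi, lo in deltas]
        return np.concatenate(parts)

    return stat


def split_envelope(
    env: EnvelopeResult, grid: RGrid, names: list[str]
) -> dict[str, EnvelopeResult]:
    """Split a stacked-statistic envelope back into one result per curve."""
    m = grid.r.size
    out = {}
    for i, name in enumerate(names):
        sl = slice(i * m, (i + 1) * m)
        out[name] = EnvelopeResult(
            r=grid.r,
            observed=env.observed[sl],
            lower=env.lower[sl],
            upper=env.upper[sl],
            expectation=env.expectation[sl],
            nsim=env.nsim,
            null_kind=env.null_kind,
            seed=env.seed,
        )
    return out


def run_curve_report(config: RunConfig) -> dict[str, Path]:
    """Size-class mingling curves and difference curves with envelopes."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    pattern = resolve_pattern(config)
    scheme = (
        TWO_CLASS_SCHEME if config.source == "dependent-marking" else config.scheme
    )
    class_idx = scheme.classify(pattern.dbh)
    occupied = tuple(
        lab
        for k, lab in enumerate(scheme.labels)
        if int(np.sum(class_idx == k)) > 0
    )
    for lab in scheme.labels:
        if lab not in occupied:
            logger.warning("size class %s empty; skipped", lab)
    deltas = _delta_pairs(occupied)
    names = [f"k_m[{c}]" for c in occupied] + [
        f"delta[{hi}-{lo}]" for hi, lo in deltas
    ]
    stat = stacked_class_statistic(config.grid, scheme, occupied, deltas)
    env = envelope(
        pattern,
        stat,
        r=np.tile(config.grid.r, len(names)),
        null_kind=config.null_kind,
        nsim=config.nsim,
        seed=config.seed,
        intensity_bandwidth=config.intensity_bandwidth,
        intensity_grid_step=config.intensity_grid_step,
    )
    parts = split_envelope(env, config.grid, names)

    import pandas as pd

    rows = []
    for name, part in parts.items():
        em = None
        if name.startswith("k_m["):
            em = expected_mingling(pattern, scheme, name[4:-1])
        for j, r in enumerate(part.r):
            rows.append(
                {
                    "statistic": name,
                    "null_kind": part.null_kind,
                    "nsim": part.nsim,
                    "seed": part.seed,
                    "r": r,
                    "observed": part.observed[j],
                    "lower": part.lower[j],
                    "upper": part.upper[j],
                    "expectation": part.expectation[j],
                    "em_d": em,
                }
            )
    curves_path = out_dir / "curve_envelopes.csv"
    pd.DataFrame(rows).to_csv(curves_path, index=False)
    manifest.add(curves_path, "curve envelopes")
    outputs = {"curves": curves_path}
    if config.plots:
        outputs["plots"] = _plot_curves(parts, out_dir, manifest)
    outputs["manifest"] = manifest.write(out_dir)
    return outputs


def _plot_mingling(pattern, summary, dens, out_dir: Path, manifest) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    levels = [lab for lab in summary.level_counts if summary.level_counts[lab]]
    data = [pattern.dbh[summary.grouped_level == lab] for lab in levels]
    axes[0].boxplot(data, tick_labels=levels)
    axes[0].set_xlabel("mingling level")
    axes[0].set_ylabel("dbh (cm)")
    for i, lev in enumerate(dens.levels):
        axes[1].plot(dens.dbh_grid, dens.density[i], label=f"M={lev}")
    axes[1].set_xlabel("dbh (cm)")
    axes[1].set_ylabel("joint density")
    axes[1].legend(fontsize=8)
    fig.tight_layout()
    path = out_dir / "mingling_report.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    manifest.add(path, "plot")
    return path


def _plot_curves(parts: dict[str, EnvelopeResult], out_dir: Path, manifest) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(parts)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.2), squeeze=False)
    for ax, (name, part) in zip(axes[0], parts.items()):
        ax.fill_between(part.r, part.lower, part.upper, color="0.8")
        ax.plot(part.r, part.expectation, "k:", lw=1)
        ax.plot(part.r, part.observed, "k-", lw=1.5)
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("r (m)")
    fig.tight_layout()
    path = out_dir / "curve_report.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    manifest.add(path, "plot")
    return path
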