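"""End-to-end orchestration: DE filter -> integrate -> graphical lasso -> reports.

``run_pipeline`` executes the full strategy on a pair of expression matrices
and a clinical table, writing per-stage outputs plus a deterministic
``manifest.json`` into the run directory.  Stage wall-clock goes to the log
and to ``timings.json``, which is the only non-deterministic output file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__ as _version
from . import diffexpr as de
from . import glasso as gl
from . import network as nw
from .io import (
    ExpressionMatrix, MIRNA, MRNA,
    read_clinical, read_expression, write_edge_list,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run (YAML-serializable)."""

    mirna_expr: str
    mrna_expr: str
    clinical: str
    rule: str
    out_dir: str
    p_threshold: float = 0.05
    upper_fc: float = 1.5
    lower_fc: float = 0.667
    de_log2: bool = False
    transform: str = "log2p1"
    scale: str = "correlation"
    center: str = "global"  # "group" removes the between-group mean shift
    rho: float = 2.0
    tol: float = 1e-4
    max_iter: int = 100
    edge_eps: float = 1e-8
    top_k: int = 20
    min_mirnas: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must lie in (0, 1]")
        if self.lower_fc <= 0 or self.upper_fc <= self.lower_fc:
            raise ValueError("need 0 < lower_fc < upper_fc")
        if self.rho < 0 or self.tol <= 0 or self.max_iter < 1:
            raise ValueError("invalid solver settings")
        if self.edge_eps < 0 or self.top_k < 1 or self.min_mirnas < 1:
            raise ValueError("invalid network settings")
        if self.rule not in de.RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.transform not in gl.TRANSFORMS or self.scale not in gl.SCALES:
            raise ValueError("invalid transform/scale")
        if self.center not in ("global", "group"):
            raise ValueError("center must be 'global' or 'group'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_json(path: Path, obj: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    Outputs written to ``config.out_dir``: de_mirna.tsv, de_mrna.tsv,
    theta.tsv, edges_full.tsv, edges_bipartite.tsv, hubs.tsv,
    multi_targets.tsv, manifest.json and timings.json.  The manifest records
    the config, per-stage feature counts and the package version, and is
    byte-identical across reruns on identical inputs; timings.json is not.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}
    flags: dict[str, bool] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                timings[name] = dt
                if exc_type is None:
                    logger.info("stage %s: done in %.2fs", name, dt)
                else:
                    logger.error("stage %s: FAILED (%s)", name, exc)
                return False

        return _T()

    try:
        with stage("load"):
            mirna = read_expression(config.mirna_expr, MIRNA)
            mrna = read_expression(config.mrna_expr, MRNA)
            clinical = read_clinical(config.clinical)
            counts["mirna_features_in"] = mirna.n_features
            counts["mrna_features_in"] = mrna.n_features
            counts["samples_in"] = mirna.n_samples
    except Exception as exc:
        raise PipelineError(f"stage 'load' failed: {exc}") from exc

    try:
        with stage("groups"):
            groups = de.assign_groups(clinical, config.rule)
            counts["group_a"] = len(groups.group_a)
            counts["group_b"] = len(groups.group_b)
            counts["samples_excluded"] = len(groups.excluded)
    except Exception as exc:
        raise PipelineError(f"stage 'groups' failed: {exc}") from exc

    try:
        with stage("diffexpr"):
            de_tabs = {}
            passing = {}
            for label, mat, fname in (
                (MIRNA, mirna, "de_mirna.tsv"),
                (MRNA, mrna, "de_mrna.tsv"),
            ):
                res = de.select_differential(
                    mat, groups, p_threshold=config.p_threshold,
                    upper_fc=config.upper_fc, lower_fc=config.lower_fc,
                    log2_transform=config.de_log2,
                )
                tab = de.results_to_frame(res, mat)
                tab.to_csv(out / fname, sep="\t", index=False)
                de_tabs[label] = tab
                passing[label] = de.passing_features(res)
            counts["mirna_de"] = len(passing[MIRNA])
            counts["mrna_de"] = len(passing[MRNA])
            if not passing[MIRNA] or not passing[MRNA]:
                empty = MIRNA if not passing[MIRNA] else MRNA
                raise ValueError(
                    f"no differentially expressed {empty} features; "
                    "consider relaxing p_threshold or the fold-change gate"
                )
    except Exception as exc:
        raise PipelineError(f"stage 'diffexpr' failed: {exc}") from exc

    try:
        with stage("integrate"):
            from .io import integrate

            Z = integrate(
                mirna.subset_features(passing[MIRNA]),
                mrna.subset_features(passing[MRNA]),
            )
            counts["features_integrated"] = Z.n_features
    except Exception as exc:
        raise PipelineError(f"stage 'integrate' failed: {exc}") from exc

    try:
        with stage("glasso"):
            cov = gl.empirical_covariance(
                Z, transform=config.transform, scale=config.scale,
                groups=groups if config.center == "group" else None,
            )
            counts["features_constant_dropped"] = len(cov.dropped_features)
            counts["features_in_model"] = cov.m
            model = gl.GraphicalLassoModel(cov, rho=config.rho)
            fit = model.fit(tol=config.tol, max_iter=config.max_iter)
            flags["glasso_converged"] = fit.converged
            if not fit.converged:
                logger.warning("graphical lasso did not converge; results flagged")
            fit.theta_frame().to_csv(out / "theta.tsv", sep="\t", index_label="feature_id")
    except Exception as exc:
        raise PipelineError(f"stage 'glasso' failed: {exc}") from exc

    try:
        with stage("network"):
            net = nw.build_network(fit, edge_eps=config.edge_eps, force=True)
            bip = nw.bipartite_view(net)
            write_edge_list(net, out / "edges_full.tsv")
            write_edge_list(bip, out / "edges_bipartite.tsv")
            counts["edges_full"] = net.n_edges
            counts["edges_bipartite"] = bip.n_edges
            hubs = nw.rank_hubs(bip, top_k=config.top_k)
            hubs.to_frame().to_csv(out / "hubs.tsv", sep="\t", index=False)
            counts["hubs_listed"] = len(hubs.ranking)
            targets = nw.multi_target_genes(bip, min_mirnas=config.min_mirnas)
            rows = [
                {"mrna": g, "n_mirnas": len(ms), "mirnas": ",".join(ms)}
                for g, ms in targets
            ]
            import pandas as pd

            pd.DataFrame(rows, columns=["mrna", "n_mirnas", "mirnas"]).to_csv(
                out / "multi_targets.tsv", sep="\t", index=False
            )
            counts["multi_target_genes"] = len(targets)
    except Exception as exc:
        raise PipelineError(f"stage 'network' failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "counts": counts,
        "flags": flags,
        "version": _version,
    }
    _write_json(out / "manifest.json", manifest)
    _write_json(out / "timings.json", {k: round(v, 6) for k, v in timings.items()})
    return manifest
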