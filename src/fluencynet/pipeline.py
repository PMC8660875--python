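"""End-to-end group-comparison analysis: configuration and orchestration.

``run_group_comparison`` executes the full chain — preprocessing, response
matrices, filtering/equating, cosine association, TMFG, network measures,
random-graph nulls, case-wise bootstrap, distribution comparisons — and
writes a reproducible report bundle (GraphML networks, JSON reports,
bootstrap CSV, run log).  All randomness derives from one master seed, so a
rerun with the same configuration reproduces every numeric output exactly.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bootstrap_compare import casewise_bootstrap, compare_groups
from .fluency_io import (
    NormalizationRules,
    build_response_matrix,
    fluency_descriptives,
    normalize_responses,
    read_lexicon,
    read_transcripts,
    read_variant_map,
    split_groups,
)
from .network_estimation import (
    cosine_association,
    equate_nodes,
    filter_min_occurrence,
    tmfg_filter,
    write_edgelist_csv,
    write_graphml,
)
from .network_metrics import compute_metrics
from .null_models import null_comparison_report, simulate_er_ensemble

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "PipelineError", "run_group_comparison"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class AnalysisConfig:
    """Configuration of a full two-group analysis run."""

    transcripts: str
    out_dir: str
    variants: str | None = None
    lexicon: str | None = None
    min_count: int = 2
    bootstrap_iters: int = 1000
    null_iters: int = 1000
    null_model: str = "gnp"
    louvain_restarts: int = 100
    bootstrap_restarts: int = 25
    equate_each_iteration: bool = True
    weighted_metrics: bool = False
    master_seed: int = 0
    overrides: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        # out_dir intentionally omitted: the log must be location-independent
        return {
            "transcripts": str(self.transcripts),
            "variants": self.variants and str(self.variants),
            "lexicon": self.lexicon and str(self.lexicon),
            "min_count": self.min_count,
            "bootstrap_iters": self.bootstrap_iters,
            "null_iters": self.null_iters,
            "null_model": self.null_model,
            "louvain_restarts": self.louvain_restarts,
            "bootstrap_restarts": self.bootstrap_restarts,
            "equate_each_iteration": self.equate_each_iteration,
            "weighted_metrics": self.weighted_metrics,
            "master_seed": self.master_seed,
        }


def _write_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_group_comparison(cfg: AnalysisConfig) -> dict:
    """Run the full two-group semantic-network comparison.

    Returns the summary report (also written to ``out_dir``).  Any stage
    failure is re-raised as :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    rng = np.random.default_rng(cfg.master_seed)
    seed_metrics = int(rng.integers(2**31))
    seed_null = int(rng.integers(2**31))
    seed_bootstrap = int(rng.integers(2**31))

    try:
        stage = "preprocess"
        rules = NormalizationRules(
            variant_map=read_variant_map(cfg.variants) if cfg.variants else {},
            lexicon=read_lexicon(cfg.lexicon) if cfg.lexicon else None,
        )
        records = [normalize_responses(r, rules) for r in read_transcripts(cfg.transcripts)]
        rec_a, rec_b = split_groups(records)

        stage = "matrices"
        mat_a = build_response_matrix(rec_a)
        mat_b = build_response_matrix(rec_b)
        label_a, label_b = mat_a.group, mat_b.group
        descriptives = fluency_descriptives(mat_a, mat_b)
        _write_json(descriptives, out / "descriptives.json")
        mat_a.to_csv(out / f"matrix_{label_a}.csv")
        mat_b.to_csv(out / f"matrix_{label_b}.csv")

        stage = "estimate"
        eq_a, eq_b = equate_nodes(
            filter_min_occurrence(mat_a, cfg.min_count),
            filter_min_occurrence(mat_b, cfg.min_count),
        )
        nets = {}
        for mat in (eq_a, eq_b):
            net = tmfg_filter(cosine_association(mat), group=mat.group)
            nets[mat.group] = net
            write_graphml(net, out / f"network_{mat.group}.graphml")
            write_edgelist_csv(net, out / f"edges_{mat.group}.csv")

        stage = "metrics"
        metrics = {
            grp: compute_metrics(
                net,
                seed=seed_metrics,
                restarts=cfg.louvain_restarts,
                weighted=cfg.weighted_metrics,
            )
            for grp, net in nets.items()
        }
        _write_json(
            {grp: m.to_report(grp, seed_metrics) for grp, m in metrics.items()},
            out / "metrics.json",
        )

        stage = "nulls"
        null_reports = {}
        for grp, net in nets.items():
            ens = simulate_er_ensemble(
                n=net.number_of_nodes(),
                m=net.number_of_edges(),
                iters=cfg.null_iters,
                seed=seed_null,
                model=cfg.null_model,
                louvain_restarts=cfg.bootstrap_restarts,
            )
            null_reports[grp] = null_comparison_report(metrics[grp], ens, group=grp)
        _write_json(null_reports, out / "nulls.json")

        stage = "bootstrap"
        boot = casewise_bootstrap(
            mat_a,
            mat_b,
            iters=cfg.bootstrap_iters,
            seed=seed_bootstrap,
            min_count=cfg.min_count,
            equate_each_iteration=cfg.equate_each_iteration,
            louvain_restarts=cfg.bootstrap_restarts,
            weighted=cfg.weighted_metrics,
        )
        with open(out / "bootstrap.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "group", "cc", "aspl", "q"])
            for side, grp in enumerate(boot.groups):
                for i in range(boot.iters):
                    writer.writerow(
                        [i, grp]
                        + [repr(float(boot.distribution(m, side).values[i]))
                           for m in ("cc", "aspl", "q")]
                    )

        stage = "compare"
        comparisons = [c.to_dict() for c in compare_groups(boot)]
        _write_json(comparisons, out / "comparison.json")

        stage = "report"
        summary = {
            "config": cfg.to_dict(),
            "version": __version__,
            "groups": [label_a, label_b],
            "n_nodes": nets[label_a].number_of_nodes(),
            "n_edges": nets[label_a].number_of_edges(),
            "seeds": {
                "metrics": seed_metrics,
                "null": seed_null,
                "bootstrap": seed_bootstrap,
            },
            "bootstrap_redraws": boot.n_redraws,
            "descriptives": descriptives,
            "metrics": {grp: m.to_report(grp, seed_metrics) for grp, m in metrics.items()},
            "comparisons": comparisons,
            "complete": True,
        }
        _write_json(summary, out / "run_log.json")
        return summary
    except Exception as exc:  # noqa: BLE001 — annotate with the failing stage
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
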