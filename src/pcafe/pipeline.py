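"""End-to-end orchestration: selection -> LDA/LOOCV -> gene mapping ->
survival screen -> enrichment, with provenance logging.

Each stage writes its table to the output directory so any later stage can
be resumed independently from disk.  The machine-readable ``summary.json``
carries the stage counts and headline numbers and contains no timestamps,
so re-running on identical inputs yields a byte-identical summary; the
per-run plain-text log records versions, the seed, and every default in
force (several upstream conventions -- prior choice, t-test variant,
sigma centering -- are deliberately explicit here because they are easy
to leave implicit and impossible to reconstruct later).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .expression import (
    read_expression,
    read_groups,
    read_probe_map,
    normalize_samples,
    map_probes,
)
from .pca import select_probes
from .classify import lda_loocv, reduced_loading, strict_loocv
from .survival import read_survival_table, screen_genes
from .enrichment import read_gmt, enrich

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage, earlier outputs remain."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    matrix: str = ""
    groups: str = ""
    probe_map: Optional[str] = None
    survival: Optional[str] = None
    gmt: Optional[str] = None
    threshold: float = 0.01
    alpha: float = 0.05
    pc: Optional[int] = None  # None = automatic identification
    t_test: str = "welch"
    survival_method: str = "logrank"
    enrich_mode: str = "fisher"
    strict: bool = False
    seed: int = 0
    outdir: str = "pcafe_run"

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Parse a flat ``key = value`` text config; kwargs win over file."""
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = value
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**_coerce(kwargs))


def _coerce(kwargs: dict) -> dict:
    casts = {
        "threshold": float,
        "alpha": float,
        "pc": lambda v: None if v in (None, "", "auto") else int(v),
        "seed": int,
        "strict": lambda v: v if isinstance(v, bool) else str(v).lower() in ("1", "true", "yes"),
    }
    return {k: casts[k](v) if k in casts else v for k, v in kwargs.items()}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages; returns the summary dict.

    Validates every referenced input path before any work starts (so a
    bad config produces no partial outputs); afterwards a stage failure
    aborts with the stage name while earlier tables stay on disk.
    """
    paths = {"matrix": cfg.matrix, "groups": cfg.groups}
    for name in ("probe_map", "survival", "gmt"):
        if getattr(cfg, name):
            paths[name] = getattr(cfg, name)
    missing = {n: p for n, p in paths.items() if not p or not Path(p).is_file()}
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("pcafe.pipeline")
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"pcafe_version": __version__, "config": {k: v for k, v in asdict(cfg).items()}}
    try:
        log.info("pcafe %s starting; config: %s", __version__, asdict(cfg))

        stage = "select"
        try:
            matrix = normalize_samples(read_expression(cfg.matrix))
            groups = read_groups(cfg.groups)
            sel = select_probes(
                matrix, groups, threshold=cfg.threshold, pc_index=cfg.pc, t_test=cfg.t_test
            )
            sel_out = sel.table.copy()
            sel_out.to_csv(outdir / "selection.tsv", sep="\t")
            ident = sel.pc_identification
            summary["selection"] = {
                "n_probes": matrix.n_probes,
                "n_samples": matrix.n_samples,
                "pc_index": ident.pc_index,
                "pc_overridden": ident.overridden,
                "pc_pvalue": float(ident.pvalues[ident.pc_index - 1]),
                "t_test": ident.t_test,
                "sigma": sel.sigma,
                "threshold": cfg.threshold,
                "n_selected": int(sel.table["selected"].sum()),
            }
            log.info("selection: %s", summary["selection"])
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineStageError(stage, exc) from exc

        stage = "classify"
        try:
            if cfg.strict:
                disc = strict_loocv(matrix, groups, threshold=cfg.threshold, pc_index=cfg.pc)
            else:
                feature = reduced_loading(matrix, sel, sel.pc_identification.pc_index)
                disc = lda_loocv(feature, groups)
            cls_out = pd.DataFrame(
                {
                    "feature": disc.feature,
                    "predicted": disc.predictions,
                    "true": disc.truth,
                }
            )
            cls_out.index.name = "sample_id"
            cls_out.to_csv(outdir / "classification.tsv", sep="\t")
            summary["classification"] = {
                "strict_loocv": cfg.strict,
                "accuracy": disc.accuracy,
                "confusion": {
                    f"pred_{p}|true_{t}": int(disc.confusion.loc[p, t])
                    for p in disc.confusion.index
                    for t in disc.confusion.columns
                },
            }
            log.info("classification: %s", summary["classification"])
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

        gene_list = None
        if cfg.probe_map:
            stage = "map-genes"
            try:
                pmap = read_probe_map(cfg.probe_map)
                gene_list, unmapped = map_probes(sel.selected_probes, pmap)
                (outdir / "genes.txt").write_text("\n".join(gene_list) + "\n")
                (outdir / "unmapped_probes.txt").write_text("\n".join(unmapped) + "\n")
                summary["genes"] = {"n_genes": len(gene_list), "n_unmapped_probes": len(unmapped)}
                log.info("map-genes: %s", summary["genes"])
            except Exception as exc:
                raise PipelineStageError(stage, exc) from exc

        if cfg.survival:
            stage = "survival"
            try:
                cohorts = read_survival_table(cfg.survival, genes=gene_list)
                screen = screen_genes(cohorts, alpha=cfg.alpha, method=cfg.survival_method)
                screen.to_csv(outdir / "survival.tsv", sep="\t", index=False)
                flagged = screen.loc[screen["flagged"], "gene"].tolist()
                summary["survival"] = {
                    "method": cfg.survival_method,
                    "alpha": cfg.alpha,
                    "n_screened": len(screen),
                    "n_flagged": len(flagged),
                    "flagged_genes": flagged,
                }
                log.info("survival: %s", summary["survival"])
            except Exception as exc:
                raise PipelineStageError(stage, exc) from exc

        if cfg.gmt:
            stage = "enrich"
            try:
                collection = read_gmt(cfg.gmt)
                query = summary.get("survival", {}).get("flagged_genes") or gene_list
                if not query:
                    raise ValueError("no gene list available for enrichment (need probe_map)")
                table = enrich(query, collection, mode=cfg.enrich_mode)
                table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
                summary["enrichment"] = {
                    "mode": cfg.enrich_mode,
                    "n_sets": len(table),
                    "n_enriched": int((table["fdr"] < cfg.alpha).sum()),
                }
                log.info("enrichment: %s", summary["enrichment"])
            except Exception as exc:
                raise PipelineStageError(stage, exc) from exc

        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
        )
        log.info("done")
    finally:
        log.removeHandler(handler)
        handler.close()
    return summary
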