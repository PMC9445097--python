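"""End-to-end orchestration: manifest in, analysis tables and reports out.

A batch is described by a manifest CSV mapping ``specimen_id`` to an
adjacency-matrix path (and optionally a taxon name).  ``run_pipeline``
computes per-specimen parameters and module reports, the pooled parameter
table, ordinations, Mann–Whitney grids, and FDA reports, and writes a
machine-readable summary carrying the full effective configuration and
input checksums so that any run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import pandas as pd

from . import __version__
from .network import read_adjacency, read_trait_table, write_edge_list, write_graphml
from .parameters import compute_parameters, parameter_table, PARAMETER_COLUMNS
from .modules import detect_modules
from .stats import pca, ppca, fda, group_battery

log = logging.getLogger("skullnet")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run (echoed into outputs)."""

    manifest: str
    out_dir: str
    traits: str | None = None
    tree: str | None = None
    low_degree_rule: str = "exclude"       # clustering-coefficient rule
    sd_rule: str = "sample"                # heterogeneity sd rule
    gtom_order: int = 1
    wilcoxon_sidedness: str = "greater"
    alpha: float = 0.05
    pca_standardize: bool = True
    z_continuity: bool = False
    fda_basis: str = "linear"
    groupings: tuple[str, ...] = ()
    fda_targets: tuple[str, ...] = ()
    strict: bool = False
    seed: int = 0

    def as_dict(self) -> dict:
        d = asdict(self)
        d["groupings"] = list(self.groupings)
        d["fda_targets"] = list(self.fda_targets)
        return d


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# produced by skullnet {__version__}\n")
        df.to_csv(fh)


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis; returns the run-report dict (also written).

    Per-specimen failures are reported and the batch continues, unless
    ``strict`` — then the run aborts with nonzero status and no pooled
    outputs are written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(config.manifest, sep=None, engine="python", dtype=str)
    if "specimen_id" not in manifest.columns or "path" not in manifest.columns:
        raise PipelineError("manifest needs columns: specimen_id, path")
    base = Path(config.manifest).parent

    checksums = {config.manifest: _sha256(config.manifest)}
    vectors, module_summaries, failures = {}, {}, {}
    for _, row in manifest.iterrows():
        sid = str(row["specimen_id"]).strip()
        path = Path(row["path"])
        if not path.is_absolute():
            path = base / path
        taxon = str(row.get("taxon", sid) or sid)
        try:
            net = read_adjacency(str(path), specimen_id=sid, taxon=taxon)
            checksums[str(path)] = _sha256(path)
            report = detect_modules(
                net,
                m=config.gtom_order,
                alpha=config.alpha,
                sidedness=config.wilcoxon_sidedness,
            )
            vectors[sid] = compute_parameters(
                net,
                module_report=report,
                low_degree_rule=config.low_degree_rule,
                sd_rule=config.sd_rule,
            )
            module_summaries[sid] = report.summary()
            spec_dir = out / "specimens" / sid
            spec_dir.mkdir(parents=True, exist_ok=True)
            assign = pd.DataFrame(
                sorted(report.partition.assignment.items()),
                columns=["node", "module"],
            ).set_index("node")
            _write_csv(assign, spec_dir / "modules.csv")
            (spec_dir / "dendrogram.nwk").write_text(report.dendrogram.to_newick() + "\n")
            (spec_dir / "report.json").write_text(
                json.dumps(report.summary(), indent=2, sort_keys=True) + "\n"
            )
            write_edge_list(net, str(spec_dir / "edges.tsv"))
            write_graphml(net, str(spec_dir / "network.graphml"))
        except Exception as exc:  # per-specimen isolation
            failures[sid] = str(exc)
            log.error("specimen %s failed: %s", sid, exc)
            if config.strict:
                raise PipelineError(f"strict mode: specimen {sid} failed: {exc}") from exc

    if not vectors:
        raise PipelineError("no specimen validated; nothing to pool")

    table = parameter_table(vectors)
    _write_csv(table, out / "parameters.csv")

    ordinations = []
    ord_table = table
    if config.pca_standardize:
        constant = [c for c in table.columns if table[c].nunique() <= 1]
        if constant:
            log.warning(
                "dropping constant column(s) %s from ordinations "
                "(zero variance under standardization)", constant,
            )
            ord_table = table.drop(columns=constant)
    if len(ord_table) >= 2 and ord_table.shape[1] >= 2:
        ordn = pca(ord_table, standardize=config.pca_standardize)
        ordinations.append(ordn)
        _write_csv(ordn.scores, out / "pca_scores.csv")
        _write_csv(ordn.loadings, out / "pca_loadings.csv")
        if config.tree:
            tree = dendropy.Tree.get(path=config.tree, schema="newick")
            checksums[config.tree] = _sha256(config.tree)
            p_ordn = ppca(ord_table, tree, standardize=config.pca_standardize)
            ordinations.append(p_ordn)
            _write_csv(p_ordn.scores, out / "ppca_scores.csv")
            _write_csv(p_ordn.loadings, out / "ppca_loadings.csv")

    test_grids, fda_reports = {}, {}
    if config.traits:
        traits = read_trait_table(config.traits).loc[list(table.index)]
        checksums[config.traits] = _sha256(config.traits)
        for grouping in config.groupings:
            grid = group_battery(
                table, traits, grouping,
                ordinations=ordinations, continuity=config.z_continuity,
            )
            _write_csv(grid, out / f"tests_{grouping}.csv")
            test_grids[grouping] = grid.to_dict(orient="index")
        for target in config.fda_targets:
            result = fda(table, traits[target], basis=config.fda_basis)
            fda_reports[target] = {
                "misclassification_error": result.misclassification_error,
                "n_errors": result.n_errors,
                "confusion": result.confusion.to_dict(orient="index"),
            }
            (out / f"fda_{target}.json").write_text(
                json.dumps(fda_reports[target], indent=2, sort_keys=True) + "\n"
            )

    report = {
        "version": __version__,
        "config": config.as_dict(),
        "input_checksums": checksums,
        "n_specimens": len(vectors),
        "failures": failures,
        "modules": module_summaries,
        "variance_explained": {
            o.kind: [float(v) for v in o.variance_explained] for o in ordinations
        },
        "fda": fda_reports,
    }
    (out / "run_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
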