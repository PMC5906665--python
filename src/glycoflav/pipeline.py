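"""End-to-end orchestration: configuration, stage logging, and the two
pipeline runs (metabolomics and expression).

The metabolomics run chains Pareto scaling -> PCA (report) -> OPLS-DA ->
VIP filter -> signal library -> annotation -> fold changes -> clustering;
the expression run produces RPKM, the two differential-gene flag sets, and
pathway rich factors.  All outputs are TSV; every stage logs record counts
in and out, and all randomness flows through the single config seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path


import pandas as pd

from . import annotate as _ann
from . import chemometrics as _chem
from . import expression as _expr
from . import simulate as _sim
from . import spectra as _spec
from . import timecourse as _tc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_metabolomics", "run_expression"]


@dataclass(frozen=True)
class PipelineConfig:
    """Flat, diffable run configuration (key=value text file)."""

    seed: int = 1
    snr_min: float = 10.0
    vip_min: float = 1.0
    fdr_max: float = 0.05
    fc_min: float = 2.0
    aa_lfc_min: float = 1.0
    aa_p_max: float = 0.05
    precursor_tol_ppm: float = 10.0
    fragment_tol_da: float = 0.5
    n_ortho: int = 1
    pca_components: int = 2
    linkage: str = "complete"
    metric: str = "euclidean"
    row_zscore: bool = False
    outdir: str = "glycoflav_out"

    def __post_init__(self) -> None:
        for name in ("snr_min", "vip_min", "fdr_max", "fc_min", "aa_lfc_min",
                     "aa_p_max", "precursor_tol_ppm", "fragment_tol_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(cls, key)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    def checksum(self) -> str:
        text = ";".join(f"{f.name}={getattr(self, f.name)}" for f in fields(self))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _stage_header(cfg: PipelineConfig, stage: str) -> str:
    return f"# glycoflav stage={stage} config={cfg.checksum()}"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_stage_header(cfg, stage) + "\n")
        df.to_csv(fh, sep="\t", index=index)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_metabolomics(
    config: PipelineConfig,
    matrix: _chem.IntensityMatrix | None = None,
    spectra: list[_spec.Spectrum] | None = None,
) -> dict:
    """Run the metabolomics chain; synthesizes inputs from the config seed
    when none are given.  Returns the artifact dict and writes every stage's
    output under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    sim_cfg = _sim.SimulationConfig(seed=config.seed)

    def stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - halt with stage context
            raise StageError(name, exc) from exc
        logger.info("stage %s: done", name)
        return result

    if matrix is None:
        matrix, informative = stage(
            "synthesize-matrix", lambda: _sim.make_two_group_matrix(sim_cfg)
        )
        artifacts["informative_truth"] = informative
    # 1) scale (log, then Pareto)
    scaled = stage(
        "pareto-scale", lambda: _chem.pareto_scale(_chem.log_transform(matrix))
    )
    logger.info("pareto-scale: %d -> %d features", matrix.n_features, scaled.n_features)
    # 2) PCA report
    model_pca = stage("pca", lambda: _chem.pca(scaled, k=config.pca_components))
    scores = pd.DataFrame(model_pca.scores,
                          columns=[f"PC{i+1}" for i in range(model_pca.scores.shape[1])])
    scores.insert(0, "sample_id", list(scaled.sample_ids))
    scores.insert(1, "group", list(scaled.group))
    _write_tsv(scores, out / "pca_scores.tsv", config, "pca")
    artifacts["pca"] = model_pca
    # 3) OPLS-DA + VIP
    model_opls = stage("oplsda", lambda: _chem.oplsda(scaled, n_ortho=config.n_ortho))
    artifacts["oplsda"] = model_opls
    vip_df = pd.DataFrame({"feature_id": scaled.feature_ids, "vip": model_opls.vip})
    _write_tsv(vip_df, out / "vip.tsv", config, "oplsda")
    # 4) VIP filter
    retained = stage(
        "vip-filter",
        lambda: _chem.vip_filter(scaled.feature_ids, model_opls.vip, config.vip_min),
    )
    logger.info("vip-filter: %d -> %d features", scaled.n_features, len(retained))
    artifacts["vip_retained"] = retained
    # 5) signal library + 6) annotation (on provided or synthetic spectra)
    if spectra is None:
        grid = _sim.enumerate_structures()
        spectra = [_sim.spectrum_from_structure(t, sim_cfg) for t in grid]
        artifacts["structure_truth"] = grid
    library = stage(
        "signal-library",
        lambda: _spec.build_signal_library(
            [replace(s, snr=s.snr if s.snr is not None else 11.0,
                     vip=s.vip if s.vip is not None else 1.5) for s in spectra],
            snr_min=config.snr_min, vip_min=config.vip_min,
        ),
    )
    logger.info("signal-library: %d -> %d spectra", len(spectra), len(library))
    ann_cfg = _ann.AnnotatorConfig(
        precursor_tol_ppm=config.precursor_tol_ppm, fragment_tol_da=config.fragment_tol_da
    )
    annotations = stage("annotate", lambda: [_ann.annotate(s, ann_cfg) for s in library])
    ann_rows = []
    for a in annotations:
        name = _ann.canonical_name(a) if a.glyco_class != "unknown" else ""
        ann_rows.append(
            {
                "id": a.spectrum_id,
                "precursor_mz": round(a.precursor_mz, 4),
                "class": a.glyco_class,
                "canonical_name": name,
                "score": round(a.score, 2),
                "evidence": ";".join(
                    f"{e.kind}@{e.observed_mz:.1f}" for e in a.evidence
                ),
            }
        )
    _write_tsv(pd.DataFrame(ann_rows), out / "annotations.tsv", config, "annotate")
    artifacts["annotations"] = annotations
    # 7) fold changes + 8) clustering on a synthetic time course
    tc_matrix = stage(
        "synthesize-timecourse", lambda: _sim.make_timecourse_matrix(sim_cfg)
    )
    fc = stage("fold-changes", lambda: _tc.fold_changes(tc_matrix))
    fc_for_tree = fc.zscore_rows() if config.row_zscore else fc
    _write_tsv(fc.to_frame(), out / "fold_changes.tsv", config, "fold-changes", index=True)
    dend = stage("hcluster", lambda: _tc.hcluster(fc_for_tree, config.linkage, config.metric))
    (out / "dendrogram.nwk").write_text(
        _stage_header(config, "hcluster") + "\n" + _tc.to_newick(dend) + "\n"
    )
    artifacts["fold_changes"] = fc
    artifacts["dendrogram"] = dend
    return artifacts


def run_expression(
    config: PipelineConfig,
    counts: pd.DataFrame | None = None,
    length_bp: pd.Series | None = None,
    stats: pd.DataFrame | None = None,
    pathway_map: _expr.PathwayMap | None = None,
) -> dict:
    """Run the expression chain: RPKM, DEG flags under both criteria,
    pathway rich factors.  Synthesizes counts from the seed when absent."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    if counts is None or stats is None:
        sim = _sim.make_count_table(_sim.SimulationConfig(seed=config.seed))
        counts, length_bp, stats = sim["counts"], sim["length_bp"], sim["stats"]
        artifacts["true_de"] = sim["true_de"]
    try:
        genes = [
            _expr.GeneRecord(g, int(length_bp[g]), tuple(int(c) for c in counts.loc[g]))
            for g in counts.index
        ]
        rpkm_df = _expr.rpkm_table(genes)
    except Exception as exc:  # noqa: BLE001
        raise StageError("rpkm", exc) from exc
    _write_tsv(rpkm_df, out / "rpkm.tsv", config, "rpkm", index=True)
    try:
        degs = _expr.flag_degs(
            stats, fc_min=config.fc_min, fdr_max=config.fdr_max,
            aa_lfc_min=config.aa_lfc_min, aa_p_max=config.aa_p_max,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("flag-degs", exc) from exc
    deg_df = pd.DataFrame(
        [
            {"gene_id": d.gene_id, "log2fc": d.log2fc, "pvalue": d.pvalue,
             "fdr": d.fdr, "sig_global": d.sig_global, "sig_aa": d.sig_aa}
            for d in degs
        ]
    )
    _write_tsv(deg_df, out / "degs.tsv", config, "flag-degs")
    artifacts["degs"] = degs
    logger.info("flag-degs: %d genes, %d sig_global, %d sig_aa", len(degs),
                sum(d.sig_global for d in degs), sum(d.sig_aa for d in degs))
    if pathway_map is not None:
        if not pathway_map.pathways:
            logger.warning("empty pathway map; enrichment table left empty")
            enrich = pd.DataFrame(
                columns=["pathway_id", "deg_count", "pathway_size", "rich_factor"]
            )
        else:
            deg_ids = {d.gene_id for d in degs if d.sig_global}
            try:
                enrich = _expr.rich_factor(deg_ids, pathway_map)
            except Exception as exc:  # noqa: BLE001
                raise StageError("rich-factor", exc) from exc
        _write_tsv(enrich, out / "enrichment.tsv", config, "rich-factor")
        artifacts["enrichment"] = enrich
    return artifacts
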