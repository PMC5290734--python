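"""Config-driven orchestration of the full analysis over a layer family.

One call (:func:`run_full_analysis`) reproduces the whole workflow on any
family: per-layer structural and spectral summaries with matched ER and
configuration null ensembles, per-layer weak-tie tables, the cross-layer
Venn/common-set report, the subtractive IN/OUT analysis, and the ranked
candidate table — all written as TSVs with the run configuration and seeds
embedded, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import multilayer, null_models, spectral, structural, weak_ties
from .graph_io import DISEASE, LayerFamily, family_from_manifest

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of a full analysis run."""

    manifest: str = ""
    out_dir: str = "complexome_out"
    confidence_threshold: float = 0.50
    null_model_list: tuple[str, ...] = ("ER", "configuration")
    n_realizations: int = 20
    seed: int = 0
    bc_quantile: float = 0.9
    k_quantile: float = 0.5
    beta_quantile: float = 0.9
    overlap_quantile: float = 0.1
    min_layers_bc: int = 4
    require_weak_tie: bool = True
    annotation_file: str = ""

    def validate(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must be in [0, 1]")
        for q in (self.bc_quantile, self.k_quantile, self.beta_quantile, self.overlap_quantile):
            if not 0.0 < q < 1.0:
                raise ValueError("quantiles must lie in (0, 1)")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        for m in self.null_model_list:
            if m.upper() != "ER" and m.lower() not in ("configuration", "config"):
                raise ValueError(f"unknown null model {m!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "null_model_list" in data:
            data["null_model_list"] = tuple(data["null_model_list"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage child seed: adding a stage never perturbs another's
    randomness.  Always < 2**31."""
    return zlib.crc32(f"{stage}:{master_seed}".encode()) & 0x7FFFFFFF


_NULL_METRICS = ["mean_degree", "mean_clustering", "diameter", "assortativity",
                 "count_zero", "count_minus_one"]


def layer_table(
    family: LayerFamily,
    null_model_list: tuple[str, ...] = (),
    n_realizations: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-layer structural + spectral summary, one row per layer, with
    null-ensemble means/sds appended when null models are requested."""
    rows = []
    for (tissue, cond), net in sorted(family.items()):
        s = structural.structural_summary(net)
        sp = spectral.spectral_summary(net)
        row = {
            "tissue": tissue, "condition": cond,
            "N": s.n_nodes, "N_C": s.n_edges,
            "mean_degree": s.mean_degree, "mean_clustering": s.mean_clustering,
            "diameter": s.diameter, "lcc_fraction": s.lcc_fraction,
            "assortativity": s.assortativity,
            "corr_k_cc": s.corr_k_cc, "corr_k_betweenness": s.corr_k_betweenness,
            "count_zero": sp.count_zero, "count_minus_one": sp.count_minus_one,
            "duplicate_bound_zero": sp.bound_zero,
            "inferred_partial_duplication": sp.inferred_partial_duplication,
            "overlap_betweenness_corr": weak_ties.overlap_betweenness_correlation(net),
        }
        for model in null_model_list:
            ens = null_models.ensemble_summary(
                net, model, metrics=_NULL_METRICS, n_realizations=n_realizations,
                seed=stage_seed(seed, f"null:{model}:{tissue}:{cond}"),
            )
            tag = "er" if model.upper() == "ER" else "config"
            for m in _NULL_METRICS:
                row[f"{tag}_{m}_mean"] = ens.mean[m]
                row[f"{tag}_{m}_sd"] = ens.sd[m]
        rows.append(row)
    return pd.DataFrame(rows)


def _write_tsv(frame: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_full_analysis(
    config: RunConfig, family: LayerFamily | None = None
) -> dict[str, Path]:
    """Run the complete pipeline and write the report bundle.

    ``family`` may be passed directly (e.g. a synthetic one); otherwise it
    is built from the manifest in the config.  Returns the paths written.
    Any stage failure aborts with the stage named.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    cfg_dict.pop("out_dir")  # a location, not an analysis parameter
    provenance = [f"complexome run seed={config.seed}",
                  f"config={json.dumps(cfg_dict, sort_keys=True)}"]
    (out / "run_config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))

    stage = "load_family"
    paths: dict[str, Path] = {}
    try:
        if family is None:
            manifest = yaml.safe_load(Path(config.manifest).read_text())
            base = Path(config.manifest).parent
            if "confidence_threshold" not in manifest:
                manifest["confidence_threshold"] = config.confidence_threshold
            family = family_from_manifest(manifest, base_dir=base)
        conditions = {c for (_t, c) in family.layers}
        if len(conditions) < 2:
            raise ValueError(f"family must contain both conditions, found {sorted(conditions)}")

        stage = "fig1_table"
        table = layer_table(family, config.null_model_list,
                            config.n_realizations, config.seed)
        paths["fig1_table"] = out / "fig1_table.tsv"
        _write_tsv(table, paths["fig1_table"], provenance)

        stage = "weak_ties"
        wt_frames = []
        for (tissue, cond), net in sorted(family.items()):
            rep = weak_ties.extract_weak_ties(
                net, beta_quantile=config.beta_quantile,
                overlap_quantile=config.overlap_quantile,
            )
            frame = rep.table.copy()
            frame.insert(0, "tissue", tissue)
            frame.insert(1, "condition", cond)
            wt_frames.append(frame)
        paths["weak_ties"] = out / "weak_ties.tsv"
        _write_tsv(pd.concat(wt_frames, ignore_index=True), paths["weak_ties"], provenance)

        stage = "multilayer_venn"
        common = multilayer.common_nodes(family)
        venn = pd.DataFrame([
            {"set": "common_disease", "size": len(common.common_disease),
             "members": ";".join(sorted(map(str, common.common_disease)))},
            {"set": "common_normal", "size": len(common.common_normal),
             "members": ";".join(sorted(map(str, common.common_normal)))},
            {"set": "common_both", "size": len(common.common_both),
             "members": ";".join(sorted(map(str, common.common_both)))},
            {"set": "union_normal_disease", "size": len(common.union_normal_disease),
             "members": ";".join(sorted(map(str, common.union_normal_disease)))},
        ])
        paths["venn"] = out / "venn.tsv"
        _write_tsv(venn, paths["venn"], provenance)

        stage = "in_out"
        rows = []
        for tissue, net in sorted(family.by_condition(DISEASE).items()):
            rep = multilayer.subtractive_report(net, common.common_disease)
            rows.append({
                "tissue": tissue, "in_connections": rep.in_connections,
                "mean_out_degree": rep.mean_out_degree,
                "mean_degree": rep.mean_degree,
                "out_to_mean_degree_ratio": rep.out_to_mean_degree_ratio,
                "clustering_ratio": rep.clustering_ratio,
            })
        paths["in_out"] = out / "in_out.tsv"
        _write_tsv(pd.DataFrame(rows), paths["in_out"], provenance)

        stage = "candidates"
        report = multilayer.rank_candidates(
            family, common.common_disease,
            min_layers_bc=config.min_layers_bc,
            require_weak_tie=config.require_weak_tie,
            bc_quantile=config.bc_quantile, k_quantile=config.k_quantile,
            beta_quantile=config.beta_quantile,
            overlap_quantile=config.overlap_quantile,
        )
        evidence = report.evidence
        if config.annotation_file:
            ann = {}
            for raw in Path(config.annotation_file).read_text().splitlines():
                if raw.strip() and not raw.startswith("#"):
                    k, _, v = raw.partition("\t")
                    ann[k.strip()] = v.strip()
            evidence = multilayer.join_annotations(evidence, ann)
        paths["candidates"] = out / "candidates.tsv"
        _write_tsv(evidence, paths["candidates"], provenance)

        stage = "run_log"
        log = {
            "seed": config.seed,
            "n_layers": len(family),
            "tissues": family.tissues,
            "candidates": sorted(map(str, report.candidates)),
            "venn_counts": list(common.venn_counts),
        }
        paths["run_log"] = out / "run_log.json"
        paths["run_log"].write_text(json.dumps(log, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return paths
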