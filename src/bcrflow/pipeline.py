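"""End-to-end orchestration: correction, clustering, germlines, statistics,
SHM, tracing and sharing, with reproducibility metadata on every output."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .airr_io import Repertoire, read_rearrangements, write_rearrangements
from .chain_tracer import QueryClone, summarize_descendants, trace_relatives
from .clonal_clustering import (
    attach_germlines,
    define_clones,
    detect_threshold,
    nearest_neighbor_distances,
)
from .connectivity import clonotype_connectivity, cross_compartment_sharing
from .error_correction import CorrectionParams, correct_repertoire
from .repertoire_stats import (
    diversity_indices,
    gene_usage,
    isotype_distribution,
    top_clones_cumulative,
    treemap_table,
)
from .shm_analysis import count_mutations, hotspot_fraction, region_rs_profile

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs and stage parameters of one pipeline run."""

    inputs: dict = field(default_factory=dict)  # (donor, compartment, timepoint) -> path
    query_path: str | None = None
    out_dir: str = "bcrflow_out"
    seed: int = 0
    copy_threshold: int = 5
    max_merge_distance: int = 1
    drop_nonproductive: bool = True
    bin_width: float = 0.01
    smooth_window: int = 5
    fallback_threshold: float = 0.1
    threshold: float | None = None
    sharing_downsample: int = 10_000

    def provenance(self) -> dict:
        d = asdict(self)
        d["inputs"] = {"/".join(map(str, k)): v for k, v in self.inputs.items()}
        d["version"] = __version__
        return d


def _write_json(path: Path, payload: dict, config: PipelineConfig) -> None:
    payload = {"provenance": config.provenance(), **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in fixed order on each input repertoire:
    correct -> threshold -> cluster -> germlines -> stats/SHM, then
    cross-compartment sharing per donor and optional query tracing.

    Outputs land under ``config.out_dir``; reruns with an identical
    config produce identical files.  Any stage error aborts with the
    stage and input named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = CorrectionParams(
        copy_threshold=config.copy_threshold,
        max_merge_distance=config.max_merge_distance,
        drop_nonproductive=config.drop_nonproductive,
    )

    corrected: dict[tuple, Repertoire] = {}
    clones_by_key: dict[tuple, list] = {}
    bundle: dict = {"outputs": []}

    for key, path in sorted(config.inputs.items()):
        tag = "_".join(str(k) for k in key)
        if not Path(path).exists():
            raise FileNotFoundError(f"stage=input key={key}: missing path {path}")
        try:
            rep = read_rearrangements(path)
            rep2, report = correct_repertoire(rep, params)
            logger.info("correct %s: %d -> %d records", tag, len(rep), len(rep2))

            profile = None
            if config.threshold is None:
                try:
                    profile = detect_threshold(
                        nearest_neighbor_distances(rep2),
                        bin_width=config.bin_width,
                        smooth_window=config.smooth_window,
                        fallback_threshold=config.fallback_threshold,
                    )
                    tau = profile.threshold
                except ValueError:
                    tau = config.fallback_threshold
                    logger.warning(
                        "too few distances on %s; fallback threshold %.3f", tag, tau
                    )
                if profile is not None and profile.method == "fallback":
                    logger.warning("threshold fallback on %s", tag)
            else:
                tau = config.threshold

            clones = define_clones(rep2, tau)
            attach_germlines(rep2, clones)
            corrected[key] = rep2
            clones_by_key[key] = clones

            write_rearrangements(rep2, out / f"{tag}.corrected.tsv")
            _write_json(out / f"{tag}.correction.json", report.as_dict(), config)
            div = diversity_indices(clones)
            iso = isotype_distribution(rep2)
            hot, _ = hotspot_fraction(rep2)
            shm = [count_mutations(r).frequency for r in rep2.records
                   if r.germline_alignment]
            stats = {
                "threshold": tau,
                "threshold_method": profile.method if profile is not None else "manual",
                "diversity": div.as_dict(),
                "top10_cumulative": top_clones_cumulative(clones, 10),
                "isotypes": iso,
                "hotspot_fraction": hot,
                "mean_shm_frequency": (sum(shm) / len(shm)) if shm else None,
                "connectivity": clonotype_connectivity(clones),
            }
            _write_json(out / f"{tag}.stats.json", stats, config)
            gene_usage(rep2, "V").to_csv(out / f"{tag}.v_usage.tsv", sep="\t", index=False)
            gene_usage(rep2, "J").to_csv(out / f"{tag}.j_usage.tsv", sep="\t", index=False)
            treemap_table(clones).to_csv(out / f"{tag}.treemap.tsv", sep="\t", index=False)
            rs = [region_rs_profile(r) for r in rep2.records if r.germline_alignment]
            pd.DataFrame(
                [
                    {
                        "sequence_id": p.sequence_id,
                        "n_mutations": p.n_mutations,
                        "frequency": p.frequency,
                        **{f"{reg}_{t}": p.by_region_type.get((reg, t), 0)
                           for reg in ("FR1", "CDR1", "FR2", "CDR2", "FR3")
                           for t in ("replacement", "silent")},
                    }
                    for p in rs
                ]
            ).to_csv(out / f"{tag}.shm.tsv", sep="\t", index=False)
            bundle["outputs"].append(tag)
        except Exception as exc:  # noqa: BLE001 - annotate stage context
            raise RuntimeError(f"pipeline stage failed on input {key}: {exc}") from exc

    # per-donor cross-compartment sharing
    donors = sorted({key[0] for key in corrected})
    for donor in donors:
        comps = {
            key[1]: rep for key, rep in corrected.items()
            if key[0] == donor and key[2] == 0
        }
        if len(comps) >= 2:
            sharing = cross_compartment_sharing(
                comps, n=config.sharing_downsample, seed=config.seed
            )
            _write_json(
                out / f"{donor}.sharing.json",
                {
                    "pairs": {"|".join(sorted(k)): v for k, v in sharing.pair_counts.items()},
                    "triple": sharing.triple_count,
                    "threshold": sharing.threshold,
                },
                config,
            )

    # query tracing against each corrected repertoire set, pooled per donor
    if config.query_path:
        queries = [
            QueryClone(query_id=r.sequence_id, rearrangement=r)
            for r in read_rearrangements(config.query_path).records
        ]
        from .airr_io import concat_repertoires

        pooled = concat_repertoires(corrected.values())
        results = [trace_relatives(q, pooled, tau=config.threshold) for q in queries]
        _write_json(out / "trace_summary.json", summarize_descendants(results), config)

    bundle["out_dir"] = str(out)
    return bundle
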