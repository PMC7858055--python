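"""Pipeline orchestration: chain skew -> sites -> mfa -> synchrony ->
ancestry -> strandbias from a config mapping, skipping stages whose inputs
are absent and consolidating every result into one JSON-serializable
report."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import ancestry, gcskew, genomeio, mfa, sites, strandbias

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise PipelineError(f"config: malformed YAML ({exc})") from exc
    if not isinstance(cfg, dict):
        raise PipelineError("config: top level must be a mapping")
    for key in ("fasta", "gff", "depth_exp", "depth_stat", "tree", "traits"):
        p = cfg.get("inputs", {}).get(key)
        if p is not None and not Path(p).exists():
            raise PipelineError(f"config: input file {p!r} ({key}) does not exist")
    return cfg


def _asdict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_asdict(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute all stages whose inputs are present; return the report.

    Stages with missing inputs are skipped with a logged reason; a failing
    stage raises PipelineError naming it.
    """
    inputs = config.get("inputs", {})
    params = config.get("params", {})
    report: dict[str, Any] = {"skipped": {}}

    replicons = None
    if inputs.get("fasta"):
        try:
            replicons = genomeio.read_fasta(inputs["fasta"])
        except Exception as exc:
            raise PipelineError(f"stage genomeio: {exc}") from exc
    genes = None
    if inputs.get("gff"):
        try:
            genes = genomeio.read_gff3(inputs["gff"])
        except Exception as exc:
            raise PipelineError(f"stage genomeio: {exc}") from exc

    # --- skew ---
    calls: dict[str, gcskew.ReplicationCall] = {}
    if replicons is not None:
        try:
            sp = gcskew.SkewParams(**params.get("skew", {}))
            skew_section = {}
            for rep in replicons:
                profile = gcskew.compute_gc_skew(rep, sp)
                call = gcskew.classify_replication_mode(profile, sp)
                calls[rep.id] = call
                skew_section[rep.id] = _asdict(call)
            report["skew"] = skew_section
        except Exception as exc:
            raise PipelineError(f"stage skew: {exc}") from exc
    else:
        report["skipped"]["skew"] = "no fasta input"

    # --- sites ---
    found_sites: dict[str, dict[str, int]] = {}
    if replicons is not None:
        try:
            dp = sites.DifSearchParams(**params.get("dif", {}))
            op = sites.OriSearchParams(**params.get("ori", {}))
            site_section = {}
            for rep in replicons:
                oris = sites.find_ori(rep, op, skew_call=calls.get(rep.id))
                difs = sites.find_dif(rep, genes, dp)
                found_sites[rep.id] = {}
                if oris:
                    found_sites[rep.id]["ori"] = oris[0].position
                if difs:
                    found_sites[rep.id]["dif"] = difs[0].position
                site_section[rep.id] = {
                    "ori_candidates": [_asdict(c) for c in oris[:5]],
                    "dif_candidates": [_asdict(c) for c in difs[:5]],
                }
            report["sites"] = site_section
        except Exception as exc:
            raise PipelineError(f"stage sites: {exc}") from exc
    else:
        report["skipped"]["sites"] = "no fasta input"

    # configured sites override detected ones
    for rid, d in config.get("sites", {}).items():
        found_sites.setdefault(rid, {}).update(d)

    # --- mfa ---
    profiles: dict[str, mfa.CoverageProfile] = {}
    if inputs.get("depth_exp") and replicons is not None:
        try:
            bin_size = int(params.get("mfa", {}).get("bin_size", 1000))
            depth_exp = genomeio.read_depth_tsv(inputs["depth_exp"], replicons)
            depth_stat = (
                genomeio.read_depth_tsv(inputs["depth_stat"], replicons)
                if inputs.get("depth_stat") else None
            )
            mfa_section = {}
            for rep in replicons:
                prof = mfa.bin_coverage(depth_exp[rep.id], bin_size, rep.id)
                if depth_stat is not None:
                    stat_prof = mfa.bin_coverage(
                        depth_stat[rep.id], bin_size, rep.id, phase="stationary"
                    )
                    prof = mfa.correct_coverage(prof, stat_prof)
                else:
                    logger.info("%s: no stationary profile; correction skipped",
                                rep.id)
                prof = mfa.remove_outliers(
                    prof, mfa.OutlierParams(**params.get("outliers", {}))
                )
                profiles[rep.id] = prof
                fit = mfa.infer_replication_direction(
                    prof, ori=found_sites.get(rep.id, {}).get("ori")
                )
                mfa_section[rep.id] = _asdict(fit)
            report["mfa"] = mfa_section
        except Exception as exc:
            raise PipelineError(f"stage mfa: {exc}") from exc
    else:
        report["skipped"]["mfa"] = "no exponential-phase depth input"

    # --- synchrony ---
    sync_cfg = config.get("synchrony", {})
    if profiles and sync_cfg.get("main") and sync_cfg.get("chromid"):
        try:
            main, chromid = sync_cfg["main"], sync_cfg["chromid"]
            result = mfa.synchrony_ratios(
                profiles[main], profiles[chromid],
                found_sites[main], found_sites[chromid],
                region_halfwidth=int(sync_cfg.get("region_halfwidth", 5000)),
                tolerance=float(sync_cfg.get("tolerance", 0.15)),
            )
            report["synchrony"] = _asdict(result)
        except Exception as exc:
            raise PipelineError(f"stage synchrony: {exc}") from exc
    else:
        report["skipped"]["synchrony"] = (
            "needs coverage profiles plus synchrony.main/.chromid config"
        )

    # --- ancestry ---
    if inputs.get("tree"):
        try:
            tree = ancestry.read_tree(str(inputs["tree"]))
            if inputs.get("traits"):
                tip_states = genomeio.read_traits_tsv(inputs["traits"])
                trait_tree = ancestry.TraitTree(tree=tree, tip_states=tip_states)
            else:
                trait_tree = ancestry.map_modes_to_tree(tree, calls)
            anc = {}
            for constraint in (None, *trait_tree.alphabet):
                res = ancestry.min_changes(trait_tree, constraint)
                anc[constraint or "unconstrained"] = {
                    "min_changes": res.min_changes,
                    "n_change_edges": len(res.change_edges),
                }
            report["ancestry"] = anc
        except Exception as exc:
            raise PipelineError(f"stage ancestry: {exc}") from exc
    else:
        report["skipped"]["ancestry"] = "no tree input"

    # --- strandbias ---
    if genes is not None and replicons is not None:
        try:
            sb_section = {}
            for rep in replicons:
                s = found_sites.get(rep.id, {})
                call = calls.get(rep.id)
                ori = s.get("ori", call.predicted_ori if call else None)
                ter = s.get("ter", s.get("dif", call.predicted_ter if call else None))
                mode = call.mode if call else "bidirectional"
                if ori is None or ter is None or mode == "unpredictable":
                    continue
                layout = strandbias.ReplichoreLayout(
                    ori=ori, ter=ter, length=rep.length, mode=mode
                )
                res = strandbias.leading_lagging_ratio(genes, layout, rep.id)
                sb_section[rep.id] = _asdict(res)
            report["strandbias"] = sb_section
        except Exception as exc:
            raise PipelineError(f"stage strandbias: {exc}") from exc
    else:
        report["skipped"]["strandbias"] = "needs gff and fasta inputs"

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(_asdict(report), fh, indent=2, sort_keys=True)
    return report
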