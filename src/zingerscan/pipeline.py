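"""End-to-end orchestration of the zinger-detection analysis.

The pipeline runs, per dataset: landscape construction and enrichment-zone
derivation for the ChIPped profile and each zinger profile; composition and
per-peak classification; then, pooled across datasets: neighborhood merging
per class, de-overlapping, recurrence summaries and track-proximity tests.
Optional stages add oPOSSUM-style enrichment scoring/calls on 401 bp regions
and the shuffled-matrix null calibration. Every run is deterministic under
the corpus seed, which is echoed into all outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as _enr
from . import landscape as _lsc
from . import motifs as _motifs
from . import neighborhoods as _nbh
from . import simulate as _sim
from . import zinger as _zng

ALL_STAGES = ("zones", "classify", "neighborhoods", "proximity", "enrich")


def _config_hash(corpus_cfg: _sim.CorpusConfig) -> str:
    payload = json.dumps(
        {"datasets": [asdict(d) for d in corpus_cfg.datasets],
         "seed": corpus_cfg.seed,
         "genome_length": corpus_cfg.genome_length,
         "n_shared_regions": corpus_cfg.n_shared_regions},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def dataset_landscapes_and_zones(
    ds: dict,
    zingers: dict[str, _motifs.PFM],
    chipped_pfm: _motifs.PFM,
    floor_score: float = 70.0,
) -> dict:
    """Landscapes + derived zones for the ChIPped and zinger profiles."""
    matrix = ds["matrix"]
    ids = ds["peak_ids"]
    out = {"chipped": None, "zingers": {}}
    pwm = _motifs.pfm_to_pwm(chipped_pfm)
    lsc = _lsc.build_landscape((ids, matrix), pwm, floor_score)
    out["chipped"] = (lsc, _lsc.derive_zone(lsc))
    for name, pfm in zingers.items():
        zpwm = _motifs.pfm_to_pwm(pfm)
        zl = _lsc.build_landscape((ids, matrix), zpwm, floor_score)
        out["zingers"][name] = (zl, _lsc.derive_zone(zl))
    return out


def classify_corpus(corpus: dict, floor_score: float = 70.0) -> dict:
    """Per-dataset zones, composition estimates and per-peak flags."""
    results = {"zones": [], "composition": [], "flags": {}, "landscapes": {},
               "cooccurrence": {}}
    for ds in corpus["datasets"]:
        lz = dataset_landscapes_and_zones(
            ds, corpus["zingers"], corpus["chipped_pfms"][ds["tf"]], floor_score
        )
        chip_lsc, _ = lz["chipped"]
        # composition and flags are cross-fitted (zones from one half, counts
        # on the other) to avoid zone-selection bias; the reported zones are
        # derived from the full dataset
        comp, flags = _lsc.crossfit_composition(
            chip_lsc, {name: l for name, (l, _) in lz["zingers"].items()}
        )
        results["landscapes"][ds["dataset_id"]] = lz
        results["flags"][ds["dataset_id"]] = flags
        zinger_cols = [c for c in flags.columns if c.startswith("zinger_")]
        zpeaks = flags.loc[flags["zinger"], zinger_cols]
        if len(zpeaks) >= 2:
            results["cooccurrence"][ds["dataset_id"]] = _zng.cooccurrence_matrix(
                zpeaks.rename(columns=lambda c: c.removeprefix("zinger_"))
            )
        # planted zinger peaks are expected to score worse than chipped peaks
        scores = ds["peaks"].set_index("peak_id")["score"]
        z_scores = scores[flags.index[flags["zinger"]]]
        c_scores = scores[flags.index[flags["chipped"]]]
        score_p = (
            _zng.compare_peak_scores(z_scores, c_scores)
            if len(z_scores) and len(c_scores)
            else float("nan")
        )
        for profile, (lsc, zone) in [("chipped", lz["chipped"])] + list(lz["zingers"].items()):
            results["zones"].append(
                {
                    "dataset_id": ds["dataset_id"],
                    "profile": profile,
                    "left_bp": zone.left_bp,
                    "right_bp": zone.right_bp,
                    "score_threshold": zone.score_threshold,
                    "boundaries_found": zone.boundaries_found,
                    "threshold_found": zone.threshold_found,
                }
            )
        results["composition"].append(
            {
                "dataset_id": ds["dataset_id"],
                "tf": ds["tf"],
                "cell_line": ds["cell_line"],
                "n_peaks": comp.n_peaks,
                "raw_chipped": comp.raw_chipped,
                "raw_zinger": comp.raw_zinger,
                "raw_unidentified": comp.raw_unidentified,
                "corrected_chipped": comp.corrected_chipped,
                "corrected_zinger": comp.corrected_zinger,
                "p_zinger_scores_poorer": score_p,
            }
        )
    results["zones"] = pd.DataFrame(results["zones"])
    results["composition"] = pd.DataFrame(results["composition"])
    return results


def pooled_members(corpus: dict, flags: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Pool classified peakMax positions across datasets, per class."""
    groups = {"zinger": [], "chipped": [], "unidentified": []}
    for ds in corpus["datasets"]:
        f = flags[ds["dataset_id"]]
        peaks = ds["peaks"].set_index("peak_id")
        base = peaks[["chrom", "peakmax", "tf", "cell_line", "dataset_id", "score"]]
        groups["zinger"].append(base.loc[f.index[f["zinger"]]])
        chip = f["chipped"] & (f["chipped_score"] > 85.0)
        groups["chipped"].append(base.loc[f.index[chip]])
        groups["unidentified"].append(base.loc[f.index[f["unidentified"]]])
    return {k: pd.concat(v).reset_index() for k, v in groups.items()}


def neighborhood_analysis(
    members: dict[str, pd.DataFrame], tracks: dict[str, pd.DataFrame] | None = None
) -> dict:
    """Merge per-class neighborhoods, de-overlap, summarize, test proximity."""
    nbhds = {}
    for cls, mem in members.items():
        nb, _ = _nbh.merge_neighborhoods(mem)
        nbhds[cls] = nb
    nbhds["chipped"] = _nbh.declass_overlaps(
        nbhds["chipped"], nbhds["zinger"], nbhds["unidentified"]
    )
    summary = pd.DataFrame({cls: _nbh.recurrence_summary(nb) for cls, nb in nbhds.items()}).T
    out = {"neighborhoods": nbhds, "recurrence": summary, "proximity": None}
    if tracks:
        rows = []
        for track_name, track in tracks.items():
            for a, b in (("zinger", "chipped"), ("zinger", "unidentified"),
                         ("unidentified", "chipped")):
                fa, fb, p = _nbh.proximity_test(nbhds[a], nbhds[b], track)
                rows.append(
                    {"track": track_name, "set_a": a, "set_b": b,
                     "frac_a": fa, "frac_b": fb, "p_one_tailed": p}
                )
        out["proximity"] = pd.DataFrame(rows)
    return out


def enrichment_analysis(
    corpus: dict,
    profiles: dict[str, _motifs.PFM] | None = None,
    score_threshold: float = 85.0,
    enrich_length: int = 401,
    family_map: dict[str, str] | None = None,
    seed: int | None = None,
) -> dict:
    """oPOSSUM-style enrichment scores, calls and corrected counts.

    Profiles default to the corpus's zinger matrices; each dataset is
    trimmed to the central ``enrich_length`` bp and compared against a
    GC-matched random background of equal size.
    """
    profiles = profiles or corpus["zingers"]
    rng = np.random.default_rng(seed if seed is not None else corpus["config"].seed + 1)
    center = (_lsc.REGION_LENGTH - 1) // 2
    half = (enrich_length - 1) // 2
    sl = slice(center - half, center + half + 1)
    rows = []
    for ds in corpus["datasets"]:
        target = ds["matrix"][:, sl]
        background = _sim.generate_background_set(target, rng)
        for name, pfm in profiles.items():
            pwm = _motifs.pfm_to_pwm(pfm)
            f, k, detail = _enr.dataset_scores(pwm, target, background, score_threshold)
            rows.append(
                {"dataset_id": ds["dataset_id"], "tf": ds["tf"], "profile_id": name,
                 "fisher_log": f, "ks_log": k, **detail}
            )
    results = pd.DataFrame(rows)
    results["fisher_log"] = _enr.cap_infinite(results["fisher_log"], "fisher")
    results["ks_log"] = _enr.cap_infinite(results["ks_log"], "ks")
    per_tf = _enr.aggregate_by_tf(results)
    fisher = per_tf.pivot(index="tf", columns="profile_id", values="fisher_log")
    ks = per_tf.pivot(index="tf", columns="profile_id", values="ks_log")
    calls = _enr.enrichment_calls(fisher, ks)
    counts = _enr.corrected_profile_counts(calls, family_map)
    return {"scores": results, "per_tf_fisher": fisher, "per_tf_ks": ks,
            "calls": calls, "counts": counts}


def run_pipeline(
    corpus_cfg: _sim.CorpusConfig | None = None,
    corpus: dict | None = None,
    stages: tuple[str, ...] = ("zones", "classify", "neighborhoods", "proximity"),
    tracks: dict[str, pd.DataFrame] | None = None,
    outdir: str | Path | None = None,
    track_placement_fraction: float = 0.77,
    track_background_fraction: float = 0.13,
) -> dict:
    """Run the analysis stages on a (simulated or provided) corpus.

    Stage dependencies are enforced: classify requires zones, neighborhoods
    requires classify, proximity requires neighborhoods. Results are
    returned as a dict of DataFrames; with ``outdir`` set they are also
    written as TSV/JSON stamped with the config hash and seed.
    """
    stages = tuple(stages)
    order = {s: i for i, s in enumerate(ALL_STAGES)}
    unknown = [s for s in stages if s not in order]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    deps = {"classify": "zones", "neighborhoods": "classify", "proximity": "neighborhoods"}
    for s in stages:
        d = deps.get(s)
        if d and d not in stages:
            raise ValueError(f"stage {s!r} requires stage {d!r}")
    if corpus is None:
        if corpus_cfg is None:
            raise ValueError("either corpus_cfg or corpus must be given")
        corpus = _sim.generate_corpus(corpus_cfg)
    cfg = corpus["config"]
    bundle: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "corpus": corpus,
    }
    if "zones" in stages or "classify" in stages:
        cls = classify_corpus(corpus)
        bundle["zones"] = cls["zones"]
        if "classify" in stages:
            bundle["composition"] = cls["composition"]
            bundle["flags"] = cls["flags"]
            bundle["cooccurrence"] = cls["cooccurrence"]
    if "neighborhoods" in stages:
        members = pooled_members(corpus, bundle["flags"])
        if "proximity" in stages and tracks is None:
            track_rng = np.random.default_rng(cfg.seed + 2)
            tracks = _sim.generate_tracks(
                corpus["shared_positions"],
                cfg.genome_length,
                track_rng,
                placement_fraction=track_placement_fraction,
                background_proximal_fraction=track_background_fraction,
            )
        nb = neighborhood_analysis(members, tracks if "proximity" in stages else None)
        bundle["members"] = members
        bundle["neighborhoods"] = nb["neighborhoods"]
        bundle["recurrence"] = nb["recurrence"]
        bundle["proximity"] = nb["proximity"]
        bundle["tracks"] = tracks
    if "enrich" in stages:
        bundle["enrichment"] = enrichment_analysis(corpus)
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": bundle["config_hash"], "seed": bundle["seed"]}
    (outdir / "run.json").write_text(json.dumps(meta, indent=2) + "\n")
    for key in ("zones", "composition", "recurrence", "proximity"):
        val = bundle.get(key)
        if isinstance(val, pd.DataFrame):
            val.to_csv(outdir / f"{key}.tsv", sep="\t")
    for cls, nb in (bundle.get("neighborhoods") or {}).items():
        nb.to_csv(outdir / f"neighborhoods_{cls}.tsv", sep="\t", index=False)
    for ds_id, mat in (bundle.get("cooccurrence") or {}).items():
        mat.to_csv(outdir / f"cooccurrence_{ds_id}.tsv", sep="\t")
    if "enrichment" in bundle:
        bundle["enrichment"]["scores"].to_csv(outdir / "enrichment_scores.tsv",
                                              sep="\t", index=False)
        bundle["enrichment"]["calls"].to_csv(outdir / "enrichment_calls.tsv", sep="\t")
        bundle["enrichment"]["counts"].to_csv(outdir / "enrichment_counts.tsv", sep="\t")
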