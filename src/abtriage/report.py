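"""Per-candidate triage: run every enabled dimension and aggregate warnings.

Each dimension either produces a result or an explicit skip record (e.g. the
structure-dependent dimensions when no structure is supplied); the candidate
verdict is `pass` exactly when no dimension raised a warning. Every warning
carries its triggering value and the threshold that fired, so the triage is
auditable rather than a black-box go/no-go.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .aggregation import AggregationModel, featurize
from .fv import FvSequence, GermlineRecord, assign_germline, max_identity_search
from .interface import (ComplexPose, align_onto_reference, extract_interface,
                        ir_score, pcc_score)
from .liabilities import (HumanReference, ReferenceDistribution, cdr_profile,
                          classify_exposure, count_exposed_motifs,
                          flag_germline_conserved, humanness_score,
                          scan_ptm_motifs)
from .offtarget import AntibodyRecord, offtarget_profile, predict_offtargets
from .surface import (CoarseStructure, PatchThresholds, PROPERTY_NAMES,
                      build_centroids, compute_all_properties, compute_rsa,
                      detect_patches)


@dataclass
class TriageConfig:
    """Reference resources and warning thresholds for a triage run."""

    reference_db: Sequence[AntibodyRecord] | None = None
    germlines: Sequence[GermlineRecord] | None = None
    human_reference: HumanReference | None = None
    reference_distributions: dict[str, ReferenceDistribution] = field(default_factory=dict)
    aggregation_model: AggregationModel | None = None
    patch_thresholds: PatchThresholds | None = None
    n_centroids: int = 150
    seed: int = 0
    interface_cutoff: float = 8.0
    humanness_floor: float = 0.5
    max_high_human_offtargets: int = 10
    offtarget_min_score: float = 40.0
    percentile_band: tuple[float, float] = (0.05, 0.95)


@dataclass
class TriageReport:
    candidate_id: str
    results: dict[str, dict] = field(default_factory=dict)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def verdict(self) -> str:
        return "pass" if not self.warnings else "warn"

    def to_json_dict(self) -> dict:
        return {
            "candidate_id": self.candidate_id,
            "results": self.results,
            "warnings": [list(w) for w in self.warnings],
            "verdict": self.verdict,
        }


def _skip(report: TriageReport, dimension: str, reason: str) -> None:
    report.results[dimension] = {"skipped": True, "reason": reason}


def _round(x: float, nd: int = 6) -> float:
    return float(round(float(x), nd))


def profile_antibody(fv: FvSequence, config: TriageConfig,
                     structure: CoarseStructure | None = None,
                     reference_pose: ComplexPose | None = None,
                     self_target: str = "") -> TriageReport:
    """Run every enabled triage dimension for one candidate.

    Structure-dependent dimensions (surface, aggregation, interface, PTM
    exposure) are recorded as skipped when no structure is given. Warning
    rules follow the config thresholds; dimensions run independently.
    """
    fv = fv.annotated()
    report = TriageReport(candidate_id=fv.id)

    # --- sequence novelty -------------------------------------------------
    if config.reference_db:
        hit_full = max_identity_search(fv, [r.annotated() for r in config.reference_db], "full")
        hit_cdr6 = max_identity_search(fv, [r.annotated() for r in config.reference_db], "cdr6")
        report.results["novelty"] = {
            "max_identity_full": _round(hit_full.identity),
            "max_identity_full_db_id": hit_full.db_id,
            "max_identity_cdr6": _round(hit_cdr6.identity),
            "max_identity_cdr6_db_id": hit_cdr6.db_id,
        }
    else:
        _skip(report, "novelty", "no reference database configured")

    # --- germline drift ---------------------------------------------------
    assignment = None
    if config.germlines:
        assignment = assign_germline(fv, config.germlines)
        report.results["germline"] = {
            "vh_germline": assignment.vh_germline_id,
            "vl_germline": assignment.vl_germline_id,
            "vh_mutations": assignment.vh_mutation_count,
            "vl_mutations": assignment.vl_mutation_count,
        }
    else:
        _skip(report, "germline", "no germline database configured")

    # --- PTM liabilities --------------------------------------------------
    sites = scan_ptm_motifs(fv)
    if assignment is not None:
        sites = [flag_germline_conserved(s, fv, assignment) for s in sites]
    rsa_by_chain = None
    if structure is not None:
        if structure.rsa is None:
            compute_rsa(structure)
        rsa_by_chain = {}
        offsets: dict[str, int] = {}
        for idx, res in enumerate(structure.residues):
            rsa_by_chain.setdefault(res.chain, {})[offsets.setdefault(res.chain, 0)] = \
                float(structure.rsa[idx])
            offsets[res.chain] += 1
    exposed_count = None
    cdr_exposed_high = 0
    if rsa_by_chain is not None:
        classified = []
        for s in sites:
            rsa = rsa_by_chain.get(s.chain, {}).get(s.position)
            if rsa is None:
                continue
            classified.append(classify_exposure(s, rsa))
        sites = classified
        exposed_count = count_exposed_motifs(sites)
        cdr_exposed_high = sum(1 for s in sites if s.in_cdr and s.exposure_tier == "high"
                               and s.motif_class != "k_glycation")
    report.results["ptm"] = {
        "n_sites": len(sites),
        "n_cdr_sites": sum(1 for s in sites if s.in_cdr),
        "exposed_count": exposed_count,
        "cdr_exposed_high": cdr_exposed_high if rsa_by_chain is not None else None,
        "sites": [
            {"chain": s.chain, "position": s.position, "class": s.motif_class,
             "in_cdr": s.in_cdr, "germline_conserved": s.germline_conserved,
             "tier": s.exposure_tier}
            for s in sites
        ],
    }
    if exposed_count is not None and "exposed_ptm_count" in config.reference_distributions:
        dist = config.reference_distributions["exposed_ptm_count"]
        _, hi = dist.percentile_bounds(*config.percentile_band)
        if exposed_count > hi:
            report.warnings.append(
                ("ptm", f"exposed PTM count {exposed_count} above reference "
                        f"95th percentile {hi:g}"))
    if rsa_by_chain is not None and cdr_exposed_high > 0:
        report.warnings.append(
            ("ptm", f"{cdr_exposed_high} highly exposed CDR-located motif(s)"))

    # --- CDR profile --------------------------------------------------------
    profile = cdr_profile(fv)
    report.results["cdr_profile"] = {
        "lengths": profile.lengths,
        "charges": profile.charges,
        "total_length": profile.total_length,
        "total_charge": profile.total_charge,
    }
    for key, value in (("cdr_total_length", profile.total_length),
                       ("cdr_total_charge", profile.total_charge)):
        dist = config.reference_distributions.get(key)
        if dist is not None:
            lo, hi = dist.percentile_bounds(*config.percentile_band)
            if not lo <= value <= hi:
                report.warnings.append(
                    ("cdr_profile", f"{key} {value:g} outside reference band "
                                    f"[{lo:g}, {hi:g}]"))

    # --- humanness ----------------------------------------------------------
    if config.human_reference is not None:
        hum = {chain: humanness_score(fv.chain(chain), config.human_reference,
                                      chain=chain).score
               for chain in ("H", "L")}
        report.results["humanness"] = {c: _round(v) for c, v in hum.items()}
        for chain, value in hum.items():
            if value < config.humanness_floor:
                report.warnings.append(
                    ("humanness", f"V{chain} humanness {value:.3f} below floor "
                                  f"{config.humanness_floor:g}"))
    else:
        _skip(report, "humanness", "no human reference set configured")

    # --- off-targets ---------------------------------------------------------
    if config.reference_db:
        hits = predict_offtargets(fv, list(config.reference_db), self_target,
                                  min_score=config.offtarget_min_score)
        table = offtarget_profile(hits)
        report.results["offtarget"] = {
            "n_hits": len(hits),
            "profile": {f"{tier}:{species}": count
                        for (tier, species), count in sorted(table.items())},
        }
        high_human = table[("high", "human")]
        if high_human > config.max_high_human_offtargets:
            report.warnings.append(
                ("offtarget", f"{high_human} high-tier human off-targets "
                              f"(> {config.max_high_human_offtargets})"))
    else:
        _skip(report, "offtarget", "no reference database configured")

    # --- surface & aggregation ------------------------------------------------
    if structure is not None:
        if structure.centroids is None:
            n = min(config.n_centroids, len(structure.surface_indices()))
            build_centroids(structure, n=n, seed=config.seed)
            compute_all_properties(structure)
        if config.patch_thresholds is not None:
            patches = {prop: detect_patches(structure.centroids, prop,
                                            config.patch_thresholds)
                       for prop in PROPERTY_NAMES}
            report.results["surface"] = {
                "n_centroids": structure.n_centroids,
                "patch_counts": {prop: len(p) for prop, p in patches.items()},
                "largest_patch": {prop: max((x.n_member_residues for x in p), default=0)
                                  for prop, p in patches.items()},
            }
            if config.aggregation_model is not None:
                vector = featurize(structure, patches, panel_id=fv.id)
                agg = config.aggregation_model.score(vector)
                report.results["aggregation"] = {
                    "score": _round(agg.score), "z": _round(agg.z),
                    "flagged": agg.flagged,
                }
                if agg.flagged:
                    report.warnings.append(
                        ("aggregation", f"anomaly score {agg.score:.4f} is "
                                        f"{agg.z:.2f} sd above the reference mean"))
            else:
                _skip(report, "aggregation", "no aggregation model configured")
        else:
            _skip(report, "surface", "no patch thresholds configured")
            _skip(report, "aggregation", "no patch thresholds configured")
    else:
        _skip(report, "surface", "no structure supplied")
        _skip(report, "aggregation", "no structure supplied")

    # --- interface (only meaningful with a structure and a reference pose) ----
    if structure is not None and reference_pose is not None \
            and config.patch_thresholds is not None:
        pose = align_onto_reference(structure, reference_pose)
        pairs, emap = extract_interface(pose, config.interface_cutoff)
        ir = ir_score(pairs)
        pcc = pcc_score(pose, pairs, config.patch_thresholds) if ir > 0 else None
        report.results["interface"] = {
            "rmsd": _round(pose.rmsd),
            "ir": ir,
            "pcc": None if pcc is None else _round(pcc),
            "epitope": sorted([list(e) for e in emap.epitope]),
        }
    else:
        _skip(report, "interface", "no structure or reference pose supplied")

    return report


def write_report(reports: Sequence[TriageReport], out_dir: str | Path) -> dict:
    """One JSON per candidate plus a panel-level TSV warning matrix."""
    if not reports:
        raise ValueError("no reports to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dimensions = ["novelty", "germline", "ptm", "cdr_profile", "humanness",
                  "offtarget", "surface", "aggregation", "interface"]
    rows = []
    for report in reports:
        path = out / f"{report.candidate_id}.json"
        with open(path, "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        flagged_dims = {dim for dim, _ in report.warnings}
        rows.append([report.candidate_id]
                    + ["warn" if d in flagged_dims else
                       ("skip" if report.results.get(d, {}).get("skipped") else "ok")
                       for d in dimensions]
                    + [report.verdict])
    tsv = out / "panel_summary.tsv"
    with open(tsv, "w") as fh:
        fh.write("\t".join(["candidate"] + dimensions + ["verdict"]) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return {"summary": str(tsv),
            "reports": [str(out / f"{r.candidate_id}.json") for r in reports]}
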