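"""High-level wiring: reference panels and a ready-to-run triage configuration.

These helpers assemble the synthetic reference resources (structure panel,
patch thresholds, aggregation model, reference distributions, humanness
reference) into a :class:`~abtriage.report.TriageConfig`, deterministically
from one seed.
"""

from __future__ import annotations

import numpy as np

from .aggregation import SurfaceFeatureVector, featurize, fit_aggregation_model
from .liabilities import HumanReference, ReferenceDistribution, humanness_score
from .offtarget import AntibodyRecord
from .report import TriageConfig
from .surface import (PROPERTY_NAMES, CoarseStructure, PatchThresholds,
                      build_centroids, compute_all_properties, compute_rsa,
                      detect_patches, reference_centroid_values,
                      thresholds_from_reference)
from .synth import (StructureSpec, bundled_germlines, generate_humanness_benchmark,
                    generate_reference_sets, generate_toy_structure,
                    human_like_variants)


def prepare_structure(structure: CoarseStructure, n_centroids: int = 60,
                      seed: int = 0, rsa_points: int = 256) -> CoarseStructure:
    """RSA, centroids and properties in one pass."""
    if structure.rsa is None:
        compute_rsa(structure, n_points=rsa_points)
    if structure.centroids is None:
        n = min(n_centroids, len(structure.surface_indices()))
        build_centroids(structure, n=n, seed=seed)
        compute_all_properties(structure)
    return structure


def reference_structure_panel(seed: int, n_structures: int = 30,
                              n_residues: int = 230, n_centroids: int = 60,
                              ) -> tuple[list[SurfaceFeatureVector], PatchThresholds]:
    """An unplanted toy-structure panel: feature vectors + patch thresholds."""
    rng = np.random.default_rng(seed)
    structures = []
    for _ in range(n_structures):
        st, _ = generate_toy_structure(
            StructureSpec(n_residues=n_residues, seed=int(rng.integers(2**31))))
        prepare_structure(st, n_centroids=n_centroids, seed=seed)
        structures.append(st)
    thresholds = thresholds_from_reference(reference_centroid_values(structures))
    vectors = []
    for i, st in enumerate(structures):
        patches = {prop: detect_patches(st.centroids, prop, thresholds)
                   for prop in PROPERTY_NAMES}
        vectors.append(featurize(st, patches, panel_id=f"REF{i:03d}"))
    return vectors, thresholds


def default_config(seed: int, n_reference_structures: int = 25,
                   n_db_records: int = 120) -> TriageConfig:
    """A complete triage configuration built from the synthetic references."""
    refs = generate_reference_sets(seed, n_records=n_db_records)
    db = [AntibodyRecord(id=row["id"], vh=row["vh"], vl=row["vl"],
                         target=row["target"], species=row["species"],
                         source=row["patent"])
          for row in refs["db_rows"]]
    distributions = {name: ReferenceDistribution(name, values)
                     for name, values in refs["distributions"].items()}

    bench = generate_humanness_benchmark(seed)
    germline_chains = [g.seq for g in bundled_germlines()]
    light_variants = human_like_variants(seed + 1, "L", 30)
    human_ref = HumanReference(germline_chains + bench["human"] + light_variants)
    human_scores = [humanness_score(s, human_ref).score for s in bench["human"]]
    foreign_scores = [humanness_score(s, human_ref).score for s in bench["non_human"]]
    floor = (float(np.mean(human_scores)) + float(np.mean(foreign_scores))) / 2.0

    vectors, thresholds = reference_structure_panel(seed, n_reference_structures)
    model = fit_aggregation_model(vectors, seed=seed)

    return TriageConfig(
        reference_db=db,
        germlines=list(bundled_germlines()),
        human_reference=human_ref,
        reference_distributions=distributions,
        aggregation_model=model,
        patch_thresholds=thresholds,
        seed=seed,
        humanness_floor=floor,
    )
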