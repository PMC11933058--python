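"""abtriage: multidimensional in-silico triage of antibody Fv leads.

The toolkit profiles paired VH/VL candidates along the dry-lab selection
dimensions used in early antibody discovery: sequence novelty against a
reference database, germline drift, PTM liability motifs with solvent
exposure, surface physicochemical patches, isolation-forest anomaly
(aggregation) scoring, humanness, CDR length/charge, CDR-similarity
off-target prediction and coarse-grained interface scoring against a
reference binding pose — aggregated into a per-candidate triage report.
"""

from importlib import resources

from .fv import (CdrSet, FvSequence, GermlineAssignment, IdentityHit,
                 annotate_cdrs, assign_germline, max_identity_search,
                 pairwise_identity, read_fv_fasta, read_germline_fasta,
                 write_fv_fasta)
from .liabilities import (CdrProfile, HumanReference, HumannessScore, PtmSite,
                          ReferenceDistribution, cdr_profile, classify_exposure,
                          compare_to_reference, count_exposed_motifs,
                          flag_germline_conserved, humanness_score,
                          scan_ptm_motifs)
from .surface import (Centroid, CoarseStructure, Patch, PatchThresholds,
                      build_centroids, centroid_properties,
                      compute_all_properties, compute_rsa, detect_patches,
                      load_structure, thresholds_from_reference)
from .aggregation import (AggregationModel, AggregationScore,
                          SurfaceFeatureVector, aggregation_score, featurize,
                          fit_aggregation_model)
from .offtarget import (AntibodyRecord, OffTargetHit, cdr_similarity,
                        offtarget_profile, predict_offtargets,
                        read_antibody_db)
from .interface import (ComplexPose, EpitopeMap, InterfaceScore,
                        align_onto_reference, c_score, epitope_overlap,
                        extract_interface, ir_score, pcc_score,
                        rank_candidates)
from .report import TriageConfig, TriageReport, profile_antibody, write_report

__version__ = "0.1.0"


def checkpoint_igv_path() -> str:
    """Path to the bundled TIM3/TIGIT IgV ectodomain FASTA."""
    return str(resources.files("abtriage.data") / "checkpoint_igv_domains.fasta")
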