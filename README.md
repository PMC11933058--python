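# abtriage

Multidimensional in-silico triage of antibody Fv leads.

Early antibody discovery (phage display, hybridoma) selects candidates almost
exclusively on binding, and only late-stage wet-lab work reveals whether a
lead is actually developable: whether its sequence is novel enough to patent,
whether it carries chemical-liability motifs, whether its surface drives
aggregation, whether it is immunogenic or polyspecific, and where it binds.
`abtriage` computes all of these selection dimensions from the information
available on day one — the paired VH/VL sequence and, optionally, a 3D model
of the Fv and of the antibody–antigen complex — and aggregates them into a
per-candidate triage report with auditable warning flags.

It is written for computational antibody engineers who need a reproducible,
scriptable dry-lab funnel next to a screening campaign.

## Selection dimensions

| Dimension | Method |
|---|---|
| Sequence novelty | global-alignment identity (match 1 / mismatch 0 / gap −1; identity = matches / alignment length) of the VH+VL concatenation (`full`) or the six concatenated CDRs (`cdr6`) against a patent-style reference database; the conventional 80% uniqueness threshold corresponds to 50 differences on a 250-residue pair and 10 on a 50-residue CDR concatenation |
| Germline drift | closest heavy/light germline by the same identity, with the somatic substitution list |
| PTM liabilities | motif scan — N-X-S/T and N-X-C sequons, K-D/E glycation, N-G/S/D/T/H deamidation, D-G/S/N/T/H isomerization, D-P cleavage, M/W oxidation, C hydrolysis — tiered by relative side-chain accessibility (low ≤ 30% < medium ≤ 60% < high) and by conservation in the assigned germline |
| Surface patches | coarse one-bead-per-residue model; the surface is partitioned into N centroids (k-means, 50–250) carrying exposure-weighted Kyte–Doolittle hydrophobicity, net formal charge, screened Coulomb potential (ε(r) = 4r) and best-fit-sphere curvature; patches are connected runs of centroids beyond reference-panel quantiles |
| Aggregation risk | isolation forest over a 20-feature summary of the centroid landscape; anomaly score 2^(−E[h(x)]/c(ψ)) (higher = worse), flagged when > 2 sd above the reference-panel mean |
| Humanness | fraction of the chain's 9-mers present in a human reference set |
| CDR profile | per-CDR length and net charge (D/E = −1, K/R = +1, H = 0) vs reference distributions |
| Off-targets | CDR-similarity search (length-weighted mean per-CDR identity, 0–100) against a target-annotated database, per-target best hit, high/medium tiers, human vs non-human counts |
| Interface scoring | rigid superposition onto a reference bound pose, then PCC (physico-chemical complementarity of facing centroid pairs), IR (facing-pair count) and the within-panel C-score (mean of min-max-normalised PCC and IR); predicted epitopes support Jaccard-overlap competition calls |

## Worked example

All reference resources (germline set, antibody database, reference
distributions, aggregation model) can be synthesised deterministically from a
seed, so the example below is fully self-contained:

```python
from abtriage.pipelines import default_config, prepare_structure
from abtriage.report import profile_antibody
from abtriage.synth import (PanelSpec, StructureSpec, generate_fv_panel,
                            generate_toy_structure)

config = default_config(seed=7)
panel, _ = generate_fv_panel(PanelSpec(n=3, seed=7))
fv = panel[0]
structure, _ = generate_toy_structure(StructureSpec(seed=70))
prepare_structure(structure, n_centroids=60, seed=config.seed)

report = profile_antibody(fv, config, structure=structure)
print(fv.id, report.verdict)
print("novelty:", report.results["novelty"])
print("germline:", report.results["germline"])
print("humanness:", report.results["humanness"])
print("aggregation:", report.results["aggregation"])
print("warnings:", report.warnings)
```

prints

```
AB01 warn
novelty: {'max_identity_full': 0.803571, 'max_identity_full_db_id': 'DB26', 'max_identity_cdr6': 0.568966, 'max_identity_cdr6_db_id': 'DB30'}
germline: {'vh_germline': 'IGHV-S12', 'vl_germline': 'IGKV-S08', 'vh_mutations': 7, 'vl_mutations': 3}
humanness: {'H': 0.504587, 'L': 0.808081}
aggregation: {'score': 0.416623, 'z': -0.858367, 'flagged': False}
warnings: [('humanness', 'VH humanness 0.505 below floor 0.520031')]
```

Reading: candidate AB01's full-length sequence is 80.4% identical to its
closest database neighbour (just above the 80% uniqueness threshold, but only
56.9% on the six CDRs); it drifted 7 + 3 substitutions from its germlines;
its surface anomaly score sits 0.86 sd *below* the reference mean (no
aggregation concern); the only flag raised is a VH humanness score slightly
under the human/non-human boundary of the fixture benchmark. Every warning
carries the triggering value and the threshold that fired.

A command-line interface mirrors the library (`abtriage --help`):
subcommands `identity`, `ptm-scan`, `humanness`, `surface`, `aggregate
fit/score`, `offtarget`, `score-pose`, `fixtures` and `profile`.

## Scope notes

Homology modelling of Fv structures and docking-pose generation are out of
scope: 3D coordinates and the reference bound orientation are inputs (the
bundled generator produces toy bead-shell structures for testing). The
proprietary patent-antibody and clinical-antibody panels the dimensions are
benchmarked against in production are replaced by synthetic fixtures of
identical schema. See `docs/methods.md` for the model assumptions, parameter
defaults and known limitations.
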