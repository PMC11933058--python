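"""Synthetic fixtures: germlines, Fv panels, toy structures and reference sets.

Everything the toolkit's test surface consumes can be generated here as a
pure function of a spec plus a seed, with the planted ground truth returned
alongside. The toy structures are geometric bead shells, not folded Ig
domains: they exercise the surface operators (partitioning, patch recovery,
pose recovery), not structural realism.

The bundled germlines are synthetic human-plausible V-domain sequences built
from IGHV3-23-like and IGKV1-39-like framework templates with diversified
CDRs; all carry valid framework anchors for the CDR delimitation rules and
are mutually distant enough (>= 21 substitutions) that a query with up to 10
somatic mutations is always closest to its true germline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import GenerationError
from .fv import (FvSequence, GermlineRecord, annotate_cdrs,
                 anchor_positions)
from .surface import ONE_TO_THREE, CoarseStructure, Residue

VH_TEMPLATE = ("EVQLLESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGLEWVSAISGSGGSTYYADSVKG"
               "RFTISRDNSKNTLYLQMNSLRAEDTAVYYCAKDRSYYFDYWGQGTLVTVSS")
VL_TEMPLATE = ("DIQMTQSPSSLSASVGDRVTITCRASQSISSYLNWYQQKPGKAPKLLIYAASSLQSGVPSRFSGSG"
               "SGTDFTLTISSLQPEDFATYYCQQSYSTPPTFGQGTKVEIK")

# substitutions never introduce C/W/F/G so the anchor patterns stay unique
_SAFE_ALPHABET = "ADEHIKLMNPQRSTVY"

_N_GERMLINES = 12
_MIN_GERMLINE_DISTANCE = 21
_GERMLINE_RNG_SEED = 777001  # fixed: the bundled germlines are a constant

MOTIF_TEXT = {
    "n_glycosylation": "NAS",
    "k_glycation": "KD",
    "n_deamidation": "NG",
    "d_isomerization": "DG",
    "dp_cleavage": "DP",
    "m_oxidation": "M",
    "w_oxidation": "W",
    "c_hydrolysis": "C",
}


def _variable_positions(template: str, chain: str) -> list[int]:
    fv = FvSequence("t", template, VL_TEMPLATE) if chain == "H" else \
        FvSequence("t", VH_TEMPLATE, template)
    cdrs = annotate_cdrs(fv)
    positions: list[int] = []
    for start, end in cdrs.chain_spans(chain):  # type: ignore[arg-type]
        positions.extend(range(start, end))
    # a few framework positions, clear of every anchor
    anchors = anchor_positions(template, chain)  # type: ignore[arg-type]
    fr_candidates = [5, 12, 16, 42, 70, 74] if chain == "H" else [5, 12, 40, 60, 70]
    positions.extend(p for p in fr_candidates if p not in anchors)
    return sorted(set(positions))


@lru_cache(maxsize=1)
def bundled_germlines() -> tuple[GermlineRecord, ...]:
    """The fixed synthetic germline database (12 heavy + 12 light)."""
    rng = np.random.default_rng(_GERMLINE_RNG_SEED)
    out: list[GermlineRecord] = []
    for chain, template, prefix in (("H", VH_TEMPLATE, "IGHV-S"), ("L", VL_TEMPLATE, "IGKV-S")):
        positions = _variable_positions(template, chain)
        variants: list[str] = [template]
        while len(variants) < _N_GERMLINES:
            seq = list(template)
            for p in positions:
                seq[p] = _SAFE_ALPHABET[rng.integers(len(_SAFE_ALPHABET))]
            candidate = "".join(seq)
            distances = [sum(a != b for a, b in zip(candidate, v)) for v in variants]
            if min(distances) < _MIN_GERMLINE_DISTANCE:
                continue
            # the variant must still annotate to the template spans
            probe = FvSequence("v", candidate, VL_TEMPLATE) if chain == "H" else \
                FvSequence("v", VH_TEMPLATE, candidate)
            try:
                annotate_cdrs(probe)
            except Exception:
                continue
            variants.append(candidate)
        tag = "IGHV" if chain == "H" else "IGKV"
        for i, seq in enumerate(variants, start=1):
            out.append(GermlineRecord(f"{prefix}{i:02d}", chain, seq))  # type: ignore[arg-type]
    return tuple(out)


def write_germline_fasta(path: str | Path,
                         germlines: Sequence[GermlineRecord] | None = None) -> None:
    germlines = germlines if germlines is not None else bundled_germlines()
    with open(path, "w") as fh:
        for g in germlines:
            tag = "IGHV" if g.chain == "H" else "IGKV"
            fh.write(f">{g.id}|{tag}\n{g.seq}\n")


# ---------------------------------------------------------------------------
# Fv panels with planted mutations and PTM motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifPlant:
    motif_class: str
    chain: Literal["H", "L"]
    region: Literal["cdr", "framework"]


@dataclass(frozen=True)
class PanelSpec:
    n: int = 5
    mutation_range: tuple[int, int] = (0, 10)
    planted_motifs: tuple[MotifPlant, ...] = ()
    seed: int = 0
    id_prefix: str = "AB"


@dataclass
class PanelGroundTruth:
    germline_ids: dict[str, tuple[str, str]] = field(default_factory=dict)
    mutations: dict[str, dict[str, list[tuple[int, str, str]]]] = field(default_factory=dict)
    motif_positions: dict[str, list[tuple[str, str, int]]] = field(default_factory=dict)


def _plant_motif(seq: list[str], span_candidates: list[tuple[int, int]],
                 text: str, occupied: set[int], forbidden: set[int],
                 rng: np.random.Generator) -> int:
    starts = []
    for start, end in span_candidates:
        starts.extend(range(start, end - len(text) + 1))
    rng.shuffle(starts)
    for pos in starts:
        span = set(range(pos, pos + len(text)))
        if span & occupied or span & forbidden:
            continue
        for k, ch in enumerate(text):
            seq[pos + k] = ch
        occupied |= span
        return pos
    raise GenerationError(f"no room to plant motif {text!r} without touching anchors")


def generate_fv_panel(spec: PanelSpec,
                      germlines: Sequence[GermlineRecord] | None = None,
                      ) -> tuple[list[FvSequence], PanelGroundTruth]:
    """Sample germline pairs, apply somatic substitutions, plant PTM motifs.

    Every antibody draws one heavy and one light germline, receives a uniform
    number of substitutions (within `mutation_range`) at non-anchor positions,
    and then carries each planted motif of the spec. Ground truth lists the
    germline ids, the substitutions and the planted motif positions.
    """
    rng = np.random.default_rng(spec.seed)
    germlines = list(germlines) if germlines is not None else list(bundled_germlines())
    heavy = [g for g in germlines if g.chain == "H"]
    light = [g for g in germlines if g.chain == "L"]
    truth = PanelGroundTruth()
    panel: list[FvSequence] = []
    for i in range(spec.n):
        fv_id = f"{spec.id_prefix}{i + 1:02d}"
        gh = heavy[rng.integers(len(heavy))]
        gl = light[rng.integers(len(light))]
        truth.germline_ids[fv_id] = (gh.id, gl.id)
        truth.mutations[fv_id] = {"H": [], "L": []}
        truth.motif_positions[fv_id] = []
        chains: dict[str, list[str]] = {"H": list(gh.seq), "L": list(gl.seq)}
        occupied: dict[str, set[int]] = {"H": set(), "L": set()}
        for chain, germ in (("H", gh), ("L", gl)):
            forbidden = anchor_positions(germ.seq, chain)  # type: ignore[arg-type]
            n_mut = int(rng.integers(spec.mutation_range[0], spec.mutation_range[1] + 1))
            candidates = [p for p in range(len(germ.seq)) if p not in forbidden]
            for p in rng.choice(candidates, size=n_mut, replace=False):
                old = chains[chain][p]
                choices = [c for c in _SAFE_ALPHABET if c != old]
                new = choices[rng.integers(len(choices))]
                chains[chain][p] = new
                truth.mutations[fv_id][chain].append((int(p), old, new))
                occupied[chain].add(int(p))
        for plant in spec.planted_motifs:
            germ = gh if plant.chain == "H" else gl
            probe = FvSequence("p", gh.seq, gl.seq)
            cdrs = annotate_cdrs(probe)
            spans = cdrs.chain_spans(plant.chain)
            if plant.region == "cdr":
                span_candidates = list(spans)
            else:
                # maximal framework runs, trimmed clear of the chain termini
                in_cdr = [False] * len(germ.seq)
                for s, e in spans:
                    for p in range(s, e):
                        in_cdr[p] = True
                span_candidates = []
                run_start = None
                for p in range(8, len(germ.seq) - 8):
                    if not in_cdr[p] and run_start is None:
                        run_start = p
                    elif in_cdr[p] and run_start is not None:
                        span_candidates.append((run_start, p))
                        run_start = None
                if run_start is not None:
                    span_candidates.append((run_start, len(germ.seq) - 8))
            forbidden = anchor_positions(germ.seq, plant.chain)  # type: ignore[arg-type]
            text = MOTIF_TEXT[plant.motif_class]
            pos = _plant_motif(chains[plant.chain], span_candidates, text,
                               occupied[plant.chain], forbidden, rng)
            truth.motif_positions[fv_id].append((plant.chain, plant.motif_class, pos))
        fv = FvSequence(fv_id, "".join(chains["H"]), "".join(chains["L"]))
        try:
            fv = fv.annotated()
            base = annotate_cdrs(FvSequence("g", gh.seq, gl.seq))
            if fv.cdrs.spans() != base.spans():
                raise GenerationError(f"{fv_id}: plants shifted the CDR anchors")
        except GenerationError:
            raise
        except Exception as exc:
            raise GenerationError(f"{fv_id}: generated chain lost its anchors: {exc}")
        panel.append(fv)
    return panel, truth


# ---------------------------------------------------------------------------
# Toy structures (bead shells with planted property patches)
# ---------------------------------------------------------------------------

#: Surface-biased background composition for shell residues.
_BACKGROUND_RESIDUES = "STNQDEKRGAHPYV"

_PATCH_RESIDUES = {
    ("hydrophobicity", "intense"): "FIL",
    ("hydrophobicity", "moderate"): "LVAV",
    ("charge", "intense"): "KR",
    ("charge", "moderate"): "KSRT",
    ("potential", "intense"): "DE",
    ("potential", "moderate"): "DSET",
}


@dataclass(frozen=True)
class PatchPlant:
    property: str
    size: int
    intensity: Literal["moderate", "intense"] = "intense"


@dataclass(frozen=True)
class StructureSpec:
    n_residues: int = 230
    radii: tuple[float, float, float] = (22.0, 18.0, 15.0)
    patch_plants: tuple[PatchPlant, ...] = ()
    seed: int = 0
    chains: tuple[tuple[str, float], ...] = (("H", 0.52), ("L", 0.48))


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def generate_toy_structure(spec: StructureSpec) -> tuple[CoarseStructure, dict]:
    """A perturbed ellipsoidal bead shell with planted surface patches.

    Residues sit quasi-uniformly on the shell (surface-dominated geometry);
    each planted patch assigns characteristic residue types to a contiguous
    surface cap and its membership is returned as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    directions = _fibonacci_directions(n)
    # deterministic random orientation so caps are not tied to the poles
    q = rng.normal(size=(3, 3))
    orth, _ = np.linalg.qr(q)
    directions = directions @ orth.T
    radial_jitter = rng.normal(0.0, 0.6, size=n)
    coords = directions * (np.asarray(spec.radii) + radial_jitter[:, None])
    types = [(_BACKGROUND_RESIDUES[k]) for k in rng.integers(len(_BACKGROUND_RESIDUES), size=n)]

    truth: dict = {"patches": []}
    taken: set[int] = set()
    for plant in spec.patch_plants:
        if plant.size > n:
            raise GenerationError(f"patch size {plant.size} exceeds surface size {n}")
        key = (plant.property, plant.intensity)
        if key not in _PATCH_RESIDUES:
            raise GenerationError(f"no residue palette for plant {key}")
        seed_dir = rng.normal(size=3)
        seed_dir /= np.linalg.norm(seed_dir)
        order = np.argsort(-(directions @ seed_dir))
        members = [int(i) for i in order if int(i) not in taken][:plant.size]
        if len(members) < plant.size:
            raise GenerationError("patch plants exhausted the surface")
        palette = _PATCH_RESIDUES[key]
        for k, idx in enumerate(members):
            types[idx] = palette[k % len(palette)]
        taken.update(members)
        truth["patches"].append({"property": plant.property,
                                 "intensity": plant.intensity,
                                 "members": sorted(members)})

    residues: list[Residue] = []
    start = 0
    for chain_name, fraction in spec.chains:
        count = int(round(n * fraction))
        stop = min(n, start + count) if chain_name != spec.chains[-1][0] else n
        for i in range(start, stop):
            residues.append(Residue(chain_name, i - start + 1, types[i],
                                    tuple(coords[i])))
        start = stop
    structure = CoarseStructure(residues)
    truth["n_residues"] = len(residues)
    return structure, truth


def write_structure_pdb(structure: CoarseStructure, path: str | Path) -> None:
    """Write the bead model as a PDB file (one pseudo-atom per residue)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for r in structure.residues:
        if r.chain not in chains:
            chains[r.chain] = gemmi.Chain(r.chain)
        res = gemmi.Residue()
        res.name = ONE_TO_THREE[r.restype]
        res.seqid = gemmi.SeqId(r.index, " ")
        atom = gemmi.Atom()
        atom.name = "CA" if r.restype == "G" else "CB"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*r.coord)
        res.add_atom(atom)
        chains[r.chain].add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Binding-pose scenario (reference complex + true binder + decoys)
# ---------------------------------------------------------------------------

@dataclass
class PoseScenario:
    antigen: CoarseStructure
    reference_antibody: CoarseStructure
    candidates: dict[str, CoarseStructure]
    epitope_indices: list[int]
    paratope_indices: list[int]
    true_candidate: str = "true_binder"


_SCENARIO_BACKGROUND = "STNQGAPYH"  # neutral background so complementarity is planted, not chance


def generate_pose_scenario(seed: int, n_antigen: int = 110, n_antibody: int = 140,
                           cap_size: int = 24, jitter: float = 0.3) -> PoseScenario:
    """Reference bound pose plus one true binder and three decoys.

    The antigen exposes a charged/hydrophobic epitope cap along +x; the
    reference antibody faces it with a complementary paratope cap. Decoys are
    built so that the defect survives framework superposition: flipped
    paratope charges (clash), a retracted paratope (fewer contacts), and a
    paratope relocated to the opposite pole (faces away).
    """
    rng = np.random.default_rng(seed)

    def shell(n: int, radii: tuple[float, float, float], chains) -> tuple[np.ndarray, list[str], list[tuple[str, int]]]:
        dirs = _fibonacci_directions(n)
        coords = dirs * (np.asarray(radii) + rng.normal(0, 0.4, size=n)[:, None])
        types = [(_SCENARIO_BACKGROUND[k])
                 for k in rng.integers(len(_SCENARIO_BACKGROUND), size=n)]
        labels = []
        start = 0
        for chain_name, fraction in chains:
            count = int(round(n * fraction)) if chain_name != chains[-1][0] else n - start
            for i in range(count):
                labels.append((chain_name, start + i + 1))
            start += count
        return coords, types, labels[:n]

    # antigen at the origin, epitope on the +x cap
    ag_coords, ag_types, ag_labels = shell(n_antigen, (14.0, 13.0, 12.0), (("T", 1.0),))
    epitope = np.argsort(-ag_coords[:, 0])[:cap_size].tolist()
    for k, idx in enumerate(epitope):
        ag_types[idx] = "KF"[k % 2]

    # antibody centered beyond the antigen, paratope on its -x cap
    ab_center = np.array([14.0 + 16.0 + 0.5, 0.0, 0.0])
    ab_coords, ab_types, ab_labels = shell(n_antibody, (16.0, 14.0, 12.0),
                                           (("H", 0.54), ("L", 0.46)))
    ab_coords = ab_coords + ab_center
    paratope = np.argsort(ab_coords[:, 0])[:cap_size].tolist()
    for k, idx in enumerate(paratope):
        ab_types[idx] = "DF"[k % 2]

    def build(coords: np.ndarray, types: list[str], labels) -> CoarseStructure:
        return CoarseStructure([Residue(c, i, t, tuple(xyz))
                                for (c, i), t, xyz in zip(labels, types, coords)])

    antigen = build(ag_coords, ag_types, ag_labels)
    reference = build(ab_coords, ab_types, ab_labels)

    def jittered() -> np.ndarray:
        return ab_coords + rng.normal(0.0, jitter, size=ab_coords.shape)

    candidates: dict[str, CoarseStructure] = {}
    candidates["true_binder"] = build(jittered(), list(ab_types), ab_labels)

    clash_types = list(ab_types)
    for k, idx in enumerate(paratope):
        clash_types[idx] = "KF"[k % 2]  # same sign as the epitope charges
    candidates["decoy_charge_clash"] = build(jittered(), clash_types, ab_labels)

    retracted = jittered()
    retracted[paratope] = ab_center + (retracted[paratope] - ab_center) * 0.45
    candidates["decoy_retracted"] = build(retracted, list(ab_types), ab_labels)

    away_types = list(ab_types)
    back = np.argsort(-ab_coords[:, 0])[:cap_size].tolist()
    for para_idx, back_idx in zip(paratope, back):
        away_types[para_idx], away_types[back_idx] = (away_types[back_idx],
                                                      away_types[para_idx])
    candidates["decoy_faces_away"] = build(jittered(), away_types, ab_labels)

    return PoseScenario(antigen=antigen, reference_antibody=reference,
                        candidates=candidates, epitope_indices=epitope,
                        paratope_indices=paratope)


# ---------------------------------------------------------------------------
# Reference sets (germline FASTA, antibody database TSV, distributions JSON)
# ---------------------------------------------------------------------------

def generate_reference_sets(seed: int, out_dir: str | Path | None = None,
                            n_records: int = 200, n_targets: int = 20,
                            panel_size: int = 735) -> dict:
    """Fixture analogues of a curated antibody database and a clinical panel.

    Returns (and optionally writes) a germline FASTA, an antibody database
    TSV (>= `n_records` records over `n_targets` named targets with species
    labels) and benchmark reference distributions of size `panel_size`.
    """
    rng = np.random.default_rng(seed)
    germlines = bundled_germlines()
    panel, _ = generate_fv_panel(
        PanelSpec(n=n_records, mutation_range=(3, 25), seed=int(rng.integers(2**31)),
                  id_prefix="DB"), germlines)
    targets = [f"ANTIGEN-{i + 1:02d}" for i in range(n_targets)]
    rows = []
    for i, fv in enumerate(panel):
        rows.append({
            "id": fv.id,
            "vh": fv.vh,
            "vl": fv.vl,
            "target": targets[int(rng.integers(n_targets))],
            "species": "human" if rng.random() < 0.7 else "non-human",
            "patent": f"SYNPAT{1000 + i}",
        })
    distributions = {
        "exposed_ptm_count": np.clip(np.round(rng.normal(8.0, 3.0, size=panel_size)),
                                     0, None).tolist(),
        "cdr_total_length": np.round(rng.normal(58.0, 5.0, size=panel_size)).tolist(),
        "cdr_total_charge": np.round(rng.normal(0.0, 3.0, size=panel_size)).tolist(),
    }
    result = {"germlines": germlines, "db_rows": rows, "distributions": distributions}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_germline_fasta(out / "germlines.fasta")
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "antibody_db.tsv", sep="\t", index=False)
        with open(out / "reference_distributions.json", "w") as fh:
            json.dump(distributions, fh)
        result["paths"] = {
            "germlines": str(out / "germlines.fasta"),
            "db": str(out / "antibody_db.tsv"),
            "distributions": str(out / "reference_distributions.json"),
        }
    return result


# ---------------------------------------------------------------------------
# Humanness benchmark fixture
# ---------------------------------------------------------------------------

def human_like_variants(seed: int, chain: str, n: int, max_mutations: int = 2) -> list[str]:
    """Lightly mutated germline chains, emulating human repertoire variants."""
    rng = np.random.default_rng(seed)
    pool = [g.seq for g in bundled_germlines() if g.chain == chain]
    out = []
    for _ in range(n):
        base = pool[rng.integers(len(pool))]
        safe = [p for p in range(len(base)) if p not in anchor_positions(base, chain)]
        chars = list(base)
        for p in rng.choice(safe, size=int(rng.integers(0, max_mutations + 1)),
                            replace=False):
            choices = [c for c in _SAFE_ALPHABET if c != chars[p]]
            chars[p] = choices[rng.integers(len(choices))]
        out.append("".join(chars))
    return out


def generate_humanness_benchmark(seed: int, n_per_class: int = 30) -> dict:
    """Three labelled chain sets: human-derived, humanized and non-human.

    Human-derived chains are germline frameworks with up to 2 substitutions;
    humanized chains keep the germline frameworks but carry foreign CDRs;
    non-human chains are diverged across a quarter of all positions. The
    reference set for scoring is the bundled germline heavy/light chains.
    """
    rng = np.random.default_rng(seed)
    germlines = bundled_germlines()
    heavy = [g.seq for g in germlines if g.chain == "H"]

    def mutate(seq: str, positions: Sequence[int]) -> str:
        chars = list(seq)
        for p in positions:
            choices = [c for c in _SAFE_ALPHABET if c != chars[p]]
            chars[p] = choices[rng.integers(len(choices))]
        return "".join(chars)

    human, humanized, non_human = [], [], []
    cdr_positions = _variable_positions(VH_TEMPLATE, "H")
    for _ in range(n_per_class):
        base = heavy[rng.integers(len(heavy))]
        safe = [p for p in range(len(base))
                if p not in anchor_positions(base, "H")]
        human.append(mutate(base, rng.choice(safe, size=int(rng.integers(0, 3)),
                                             replace=False)))
        fv = FvSequence("h", base, VL_TEMPLATE)
        spans = annotate_cdrs(fv).chain_spans("H")
        cdr_idx = [p for s, e in spans for p in range(s, e)]
        humanized.append(mutate(base, cdr_idx))
        quarter = rng.choice(safe, size=len(safe) // 3, replace=False)
        non_human.append(mutate(base, quarter))
    return {"reference": heavy, "human": human, "humanized": humanized,
            "non_human": non_human}
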