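"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here:

* GenomeDiff fixtures (6 ancestors + 36 evolved clones + sample sheet)
  whose post-processing yields, by construction: 78 unique evolved
  mutations, 43 pooled ancestral, 35 retained with class counts 11/4/20
  (deletions/insertions/SNPs) and SNP-effect counts 15/1/3/1
  (nonsynonymous/synonymous/intergenic/nonsense), unique loci control = 5
  and high = 16, PFLU_4551 mutated in 12/18 control clones across 5/6
  control populations and no high clones, seven high clones with zero
  retained mutations, and per-clone counts ranging 0-5 with median 1.
* Competition-assay count tables with a known true selection coefficient.
* OD growth tables with a crossed evolution-history x assay-salinity
  interaction (adapted to the salinity you evolved under, maladapted to
  the other).
* Swarming/swimming motility tables where designated mutant clones are
  shifted on swarming only.

The GD fixture is a deterministic constraint assembly — a hand-designed
allocation satisfying all the count constraints simultaneously — with
seeded randomness confined to nuisance fields (positions, alleles, locus
names). Identical (spec, seed) pairs give byte-identical files, and every
fixture is re-verified after writing by running the actual pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import genomediff as gd
from .genomediff import MutationRecord, run_pipeline, write_gd

__all__ = [
    "GdFixtureSpec",
    "FixtureManifest",
    "EffectSpec",
    "ConstraintViolation",
    "make_gd_fixtures",
    "make_competition_data",
    "make_growth_table",
    "make_motility_table",
]

REFERENCE_SEQ = "AM181176"
PARALLEL_LOCUS = "PFLU_4551"
GENOME_LENGTH = 6_722_539

_BASES = "ACGT"


class ConstraintViolation(RuntimeError):
    """A generated fixture failed its post-write self-verification."""


@dataclass(frozen=True)
class GdFixtureSpec:
    """Targets for the GD fixture set; defaults are the study's counts."""

    n_core_ancestral: int = 20
    private_per_ancestor: tuple[int, ...] = (4, 4, 4, 4, 4, 3)
    empty_ancestors: bool = False  # write header-only ancestor files

    expected_pooled: int = 43
    expected_evolved_unique: int = 78
    expected_retained: int = 35
    expected_class_counts: tuple[int, int, int] = (11, 4, 20)  # del/ins/SNP
    expected_effect_counts: tuple[int, int, int, int] = (15, 1, 3, 1)
    expected_unique_loci: tuple[int, int] = (5, 16)  # control, high

    def __post_init__(self) -> None:
        if len(self.private_per_ancestor) != 6:
            raise ConstraintViolation("exactly six ancestors are required")
        n_anc = self.n_core_ancestral + sum(self.private_per_ancestor)
        if not self.empty_ancestors and n_anc != self.expected_pooled:
            raise ConstraintViolation(
                f"core + private ancestral mutations ({n_anc}) must equal the "
                f"expected pooled size ({self.expected_pooled})"
            )


@dataclass(frozen=True)
class FixtureManifest:
    """Ground truth recomputed from the written files."""

    seed: int
    n_files: int
    per_file_counts: dict
    n_pooled: int
    n_evolved_unique: int
    n_retained: int
    class_counts: dict
    effect_counts: dict
    unique_loci_control: int
    unique_loci_high: int
    parallel_loci: list
    per_clone_median: float
    per_clone_min: int
    per_clone_max: int

    def to_json(self, path: str | Path) -> None:
        """Atomic write: temp file in the same directory, then rename."""
        path = Path(path)
        tmp = path.with_suffix(path.suffix + ".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        os.replace(tmp, path)


# --------------------------------------------------------------------------
# Hand-designed allocation tables
#
# Abstract mutation ids map to (class, locus slot, SNP effect). Locus slots:
# "PAR" is PFLU_4551; "A".."E" are control loci (E carries the synonymous
# SNP and is excluded from locus counts); "G1".."G16" are high loci; "INT*"
# are intergenic slots (excluded from locus counts).
# --------------------------------------------------------------------------

_MUTATION_DEFS: dict[str, tuple[str, str, str]] = {
    # PFLU_4551 variants: in-frame CCG-repeat indels, a nonsynonymous SNP
    # and a premature stop.
    "P1": ("deletion", "PAR", "not_applicable"),
    "P2": ("insertion", "PAR", "not_applicable"),
    "P3": ("SNP", "PAR", "nonsynonymous"),
    "P4": ("SNP", "PAR", "nonsense"),
    # other control-treatment mutations
    "LC1": ("SNP", "A", "nonsynonymous"),
    "LC2": ("deletion", "B", "not_applicable"),
    "LC3": ("insertion", "C", "not_applicable"),
    "LC4": ("SNP", "D", "nonsynonymous"),
    "SYN1": ("SNP", "E", "synonymous"),
    "INT1": ("SNP", "INT1", "intergenic"),
    # high-treatment mutations
    "HM1": ("deletion", "G1", "not_applicable"),
    "HM2": ("SNP", "G1", "nonsynonymous"),
    "HM3": ("SNP", "G2", "nonsynonymous"),
    "HM4": ("SNP", "INT2", "intergenic"),
    "HM5": ("SNP", "INT3", "intergenic"),
    "HM6": ("deletion", "G2", "not_applicable"),
    "HM7": ("deletion", "G3", "not_applicable"),
    "HM8": ("SNP", "G3", "nonsynonymous"),
    "HM9": ("SNP", "G4", "nonsynonymous"),
    "HM10": ("deletion", "G4", "not_applicable"),
    "HM11": ("SNP", "G5", "nonsynonymous"),
    "HM12": ("deletion", "G6", "not_applicable"),
    "HM13": ("deletion", "G7", "not_applicable"),
    "HM14": ("SNP", "G7", "nonsynonymous"),
    "HM15": ("insertion", "G8", "not_applicable"),
    "HM16": ("SNP", "G8", "nonsynonymous"),
    "HM17": ("deletion", "G9", "not_applicable"),
    "HM18": ("SNP", "G10", "nonsynonymous"),
    "HM19": ("deletion", "G11", "not_applicable"),
    "HM20": ("SNP", "G12", "nonsynonymous"),
    "HM21": ("insertion", "G13", "not_applicable"),
    "HM22": ("deletion", "G14", "not_applicable"),
    "HM23": ("SNP", "G14", "nonsynonymous"),
    "HM24": ("SNP", "G15", "nonsynonymous"),
    "HM25": ("SNP", "G16", "nonsynonymous"),
}

# (population index 1..6, clone index 1..3) -> new mutations of that clone.
_CONTROL_ALLOC: dict[tuple[int, int], tuple[str, ...]] = {
    (1, 1): ("P1",), (1, 2): ("P1",), (1, 3): ("P1",),
    (2, 1): ("P2",), (2, 2): ("P2",), (2, 3): ("P2",),
    (3, 1): ("P3",), (3, 2): ("P3",), (3, 3): ("P3",),
    (4, 1): ("P1",), (4, 2): ("P1",), (4, 3): ("LC1",),
    (5, 1): ("P4",), (5, 2): ("LC2",), (5, 3): ("SYN1",),
    (6, 1): ("LC3",), (6, 2): ("LC4",), (6, 3): ("INT1",),
}

_HIGH_ALLOC: dict[tuple[int, int], tuple[str, ...]] = {
    (1, 1): ("HM1", "HM2", "HM3", "HM4", "HM5"),
    (1, 2): ("HM6", "HM7", "HM8", "HM9"),
    (1, 3): ("HM10", "HM11", "HM12"),
    (2, 1): ("HM13", "HM14", "HM15"),
    (2, 2): ("HM16", "HM17"),
    (2, 3): ("HM18",),
    (3, 1): ("HM19", "HM20"),
    (3, 2): ("HM21",),
    (3, 3): (),
    (4, 1): ("HM22", "HM23"),
    (4, 2): (), (4, 3): (),
    (5, 1): ("HM24",),
    (5, 2): (), (5, 3): (),
    (6, 1): ("HM25",),
    (6, 2): (), (6, 3): (),
}


def _draw_positions(rng: np.random.Generator, n: int) -> list[int]:
    # stay clear of the 5.000-5.002 Mb window reserved for the parallel locus
    pos = rng.choice(np.arange(1000, 4_999_000, dtype=np.int64), size=n,
                     replace=False)
    return [int(p) for p in pos]


def _gene_names(
    rng: np.random.Generator, n: int, exclude: Sequence[str] = ()
) -> list[str]:
    """Distinct PFLU_xxxx identifiers, never the parallel locus itself."""
    numbers = rng.choice(np.arange(1, 6000), size=min(n + 64, 5900),
                         replace=False)
    banned = set(exclude) | {PARALLEL_LOCUS}
    names = [f"PFLU_{int(k):04d}" for k in numbers]
    names = [nm for nm in names if nm not in banned]
    if len(names) < n:
        raise ConstraintViolation("could not draw enough distinct locus names")
    return names[:n]


def _concrete_mutation(
    rng: np.random.Generator,
    mutation_class: str,
    position: int,
    locus: str,
    snp_effect: str,
    evidence: str = "consensus",
) -> MutationRecord:
    if mutation_class == "SNP":
        detail = _BASES[rng.integers(4)]
    elif mutation_class == "insertion":
        detail = "".join(_BASES[rng.integers(4)] for _ in range(3))
    else:
        detail = f"del:{int(rng.integers(1, 1200))}"
    return MutationRecord(
        seq_id=REFERENCE_SEQ,
        position=position,
        mutation_class=mutation_class,
        allele_detail=detail,
        locus=locus,
        snp_effect=snp_effect,
        evidence=evidence,
    )


def make_gd_fixtures(
    out_dir: str | Path,
    seed: int = 0,
    spec: GdFixtureSpec | None = None,
) -> FixtureManifest:
    """Write the GD fixture set and its manifest into ``out_dir``.

    Produces 6 ancestor files (``anc1.gd`` ...), 36 evolved clone files
    (``11C.gd`` ... ``63H.gd``; first digit = population, second = clone,
    letter = salinity treatment), ``sample_sheet.csv`` and
    ``manifest.json``. The written files are immediately re-analyzed with
    the real pipeline; any mismatch with the spec's expected counts raises
    :class:`ConstraintViolation` listing the failing constraints.
    """
    spec = spec or GdFixtureSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_anc = spec.n_core_ancestral + sum(spec.private_per_ancestor)
    n_new = len(_MUTATION_DEFS)
    positions = _draw_positions(rng, n_anc + n_new)
    anc_positions = positions[:n_anc]
    new_positions = positions[n_anc:]

    # Ancestral background: a shared core (the lab strain's divergence from
    # the reference) plus a few private calls per ancestor, some of them
    # deliberately marginal/unassigned.
    anc_classes = [
        ("SNP", "nonsynonymous"), ("SNP", "synonymous"), ("deletion",
        "not_applicable"), ("insertion", "not_applicable"),
        ("SNP", "intergenic"),
    ]
    anc_names = _gene_names(rng, n_anc)
    core: list[MutationRecord] = []
    for i in range(spec.n_core_ancestral):
        cls, eff = anc_classes[int(rng.integers(len(anc_classes)))]
        evidence = "marginal" if i < 2 else "unassigned" if i == 2 else "consensus"
        locus = anc_names[i] if eff != "intergenic" else f"{anc_names[i]}/next"
        core.append(
            _concrete_mutation(rng, cls, anc_positions[i], locus, eff, evidence)
        )
    privates: list[list[MutationRecord]] = []
    offset = spec.n_core_ancestral
    for a, n_private in enumerate(spec.private_per_ancestor):
        recs = []
        for j in range(n_private):
            cls, eff = anc_classes[int(rng.integers(len(anc_classes)))]
            locus = anc_names[offset + j]
            evidence = "marginal" if j == 0 else "consensus"
            recs.append(
                _concrete_mutation(
                    rng, cls, anc_positions[offset + j], locus, eff, evidence
                )
            )
        offset += n_private
        privates.append(recs)

    # Concrete forms of the evolved mutations: resolve locus slots to names.
    slot_names: dict[str, str] = {"PAR": PARALLEL_LOCUS}
    named_slots = sorted(
        {slot for _, slot, _ in _MUTATION_DEFS.values()}
        - {"PAR", "INT1", "INT2", "INT3"}
    )
    fresh = _gene_names(rng, len(named_slots) + 6, exclude=anc_names)
    for slot, name in zip(named_slots, fresh):
        slot_names[slot] = name
    inter_pairs = fresh[len(named_slots):]
    for k, slot in enumerate(("INT1", "INT2", "INT3")):
        slot_names[slot] = f"{inter_pairs[k]}/{inter_pairs[k]}b"

    new_mutations: dict[str, MutationRecord] = {}
    par_positions = iter(
        sorted(int(p) for p in rng.choice(np.arange(5_000_000, 5_001_500),
                                          size=8, replace=False))
    )
    for idx, (mid, (cls, slot, eff)) in enumerate(_MUTATION_DEFS.items()):
        pos = next(par_positions) if slot == "PAR" else new_positions[idx]
        rec = _concrete_mutation(rng, cls, pos, slot_names[slot], eff)
        if mid == "P1":
            rec = dataclasses.replace(rec, allele_detail="del:3")  # CCG repeat
        if mid == "P2":
            rec = dataclasses.replace(rec, allele_detail="CCG")
        new_mutations[mid] = rec

    # Write ancestor files.
    per_file_counts: dict[str, int] = {}
    for a in range(6):
        recs = [] if spec.empty_ancestors else core + privates[a]
        write_gd(recs, out_dir / f"anc{a + 1}.gd")
        per_file_counts[f"anc{a + 1}"] = len(recs)

    # Write evolved clone files: founder background + allocated mutations.
    sheet_rows = []
    for treat_letter, treatment, alloc in (
        ("C", "control", _CONTROL_ALLOC),
        ("H", "high", _HIGH_ALLOC),
    ):
        for (pop, clone), mids in sorted(alloc.items()):
            clone_id = f"{pop}{clone}{treat_letter}"
            background = [
                dataclasses.replace(r, evidence="consensus")
                for r in core + privates[pop - 1]
            ]
            recs = background + [new_mutations[m] for m in mids]
            write_gd(recs, out_dir / f"{clone_id}.gd")
            per_file_counts[clone_id] = len(recs)
            sheet_rows.append(
                {
                    "clone_id": clone_id,
                    "population_id": f"{pop}{treat_letter}",
                    "treatment": treatment,
                    "role": "evolved",
                }
            )
    for a in range(6):
        sheet_rows.append(
            {
                "clone_id": f"anc{a + 1}",
                "population_id": f"anc{a + 1}",
                "treatment": "ancestor",
                "role": "ancestor",
            }
        )
    sheet = pd.DataFrame(sheet_rows)
    sheet.to_csv(out_dir / "sample_sheet.csv", index=False)

    manifest = _verify_fixture(out_dir, spec, seed, per_file_counts)
    manifest.to_json(out_dir / "manifest.json")
    return manifest


def _verify_fixture(
    out_dir: Path, spec: GdFixtureSpec, seed: int, per_file_counts: dict
) -> FixtureManifest:
    """Re-run the real pipeline on the written files and check every target."""
    res = run_pipeline(out_dir / "sample_sheet.csv", out_dir)
    sp = res["spectrum"]
    pc = res["per_clone"]
    problems = []

    def check(name, got, want):
        if got != want:
            problems.append(f"{name}: expected {want}, got {got}")

    if spec.empty_ancestors:
        check("pooled", res["n_pooled"], 0)
        check("retained", res["n_retained_unique"], spec.expected_evolved_unique)
    else:
        check("pooled", res["n_pooled"], spec.expected_pooled)
        check("evolved unique", res["n_evolved_unique"],
              spec.expected_evolved_unique)
        check("retained", res["n_retained_unique"], spec.expected_retained)
        check(
            "class counts",
            (sp.class_counts["deletion"], sp.class_counts["insertion"],
             sp.class_counts["SNP"]),
            spec.expected_class_counts,
        )
        check(
            "effect counts",
            (sp.effect_counts["nonsynonymous"], sp.effect_counts["synonymous"],
             sp.effect_counts["intergenic"], sp.effect_counts["nonsense"]),
            spec.expected_effect_counts,
        )
        check(
            "unique loci",
            (len(res["unique_loci"]["control"]), len(res["unique_loci"]["high"])),
            spec.expected_unique_loci,
        )
        par = res["parallel"]
        check("parallel loci", len(par), 1)
        if len(par) == 1:
            check("parallel locus", par["locus"].iloc[0], PARALLEL_LOCUS)
            check("parallel treatment", par["treatment"].iloc[0], "control")
            check("parallel populations", int(par["n_populations"].iloc[0]), 5)
        check("per-clone median", pc.attrs["median"], 1.0)
        check("per-clone range", (pc.attrs["min"], pc.attrs["max"]), (0, 5))
    if problems:
        raise ConstraintViolation(
            "fixture self-verification failed:\n  " + "\n  ".join(problems)
        )
    return FixtureManifest(
        seed=seed,
        n_files=len(per_file_counts),
        per_file_counts=per_file_counts,
        n_pooled=res["n_pooled"],
        n_evolved_unique=res["n_evolved_unique"],
        n_retained=res["n_retained_unique"],
        class_counts=dict(sp.class_counts),
        effect_counts=dict(sp.effect_counts),
        unique_loci_control=len(res["unique_loci"]["control"]),
        unique_loci_high=len(res["unique_loci"]["high"]),
        parallel_loci=res["parallel"].to_dict("records"),
        per_clone_median=pc.attrs["median"],
        per_clone_min=pc.attrs["min"],
        per_clone_max=pc.attrs["max"],
    )


# --------------------------------------------------------------------------
# Phenotype generators
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """Known ground-truth effects for the phenotype generators.

    ``true_S`` is the selection coefficient per competition environment
    (evolved populations beat the ancestor under high salinity, lose under
    control salinity). ``od_effect`` is the magnitude of the crossed
    history x assay interaction on OD_600 deltas; ``motility_shift`` is the
    swarming-halo increase (mm) of designated mutant clones.
    """

    true_S: dict = field(
        default_factory=lambda: {"high": 0.2, "control": -0.5}
    )
    od_effect: float = 0.15
    od_noise: float = 0.05
    motility_shift: float = 8.0
    swim_shift: float = 0.0
    motility_noise: float = 1.5

    def __post_init__(self) -> None:
        if self.od_noise < 0 or self.motility_noise < 0:
            raise ValueError("noise scales must be nonnegative")


def make_competition_data(
    effect: EffectSpec | None = None,
    n_replicates: int = 6,
    seed: int = 0,
    start_count: float = 1e5,
    growth_factor: float = 100.0,
    noise: bool = True,
) -> pd.DataFrame:
    """Competition-assay count table with known true S.

    Start counts sit at the protocol value; end counts are such that the
    log-ratio difference equals the true S, plus Poisson plating noise on
    every count when ``noise`` is on. Columns: replicate, environment,
    evolved_start, evolved_end, ancestor_start, ancestor_end.
    """
    effect = effect or EffectSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for env, s_true in effect.true_S.items():
        for rep in range(n_replicates):
            a_start = start_count
            a_end = start_count * growth_factor
            e_start = start_count
            e_end = start_count * growth_factor * np.exp(s_true)
            vals = [e_start, e_end, a_start, a_end]
            if noise:
                vals = [max(int(rng.poisson(v)), 1) for v in vals]
            rows.append(
                {
                    "replicate": rep,
                    "environment": env,
                    "evolved_start": vals[0],
                    "evolved_end": vals[1],
                    "ancestor_start": vals[2],
                    "ancestor_end": vals[3],
                }
            )
    return pd.DataFrame(rows)


def make_growth_table(
    effect: EffectSpec | None = None,
    clones_per_population: int = 9,
    n_populations: int = 6,
    n_replicates: int = 3,
    seed: int = 0,
    noise: bool = True,
) -> pd.DataFrame:
    """OD_600 growth table with the trade-off interaction structure.

    Clones evolved under a salinity grow better than the ancestor when
    assayed at that salinity and worse at the other: the group-mean deltas
    follow the (+, -, -, +) sign pattern over history x assay. Ancestor
    rows (history = "ancestor") are included so deltas can be recomputed
    by ancestor-standardization downstream.
    """
    effect = effect or EffectSpec()
    rng = np.random.default_rng(seed)
    baseline = {"control": 1.0, "high": 0.6}
    rows = []
    sd = effect.od_noise if noise else 0.0
    for assay in ("control", "high"):
        for a in range(6):
            for rep in range(6):
                od = baseline[assay] + rng.normal(0.0, sd)
                rows.append(
                    {
                        "history": "ancestor",
                        "assay_salinity": assay,
                        "population": f"anc{a + 1}",
                        "clone": f"anc{a + 1}",
                        "replicate": rep,
                        "od600": max(od, 0.0),
                    }
                )
        for history in ("control", "high"):
            sign = 1.0 if history == assay else -1.0
            for pop in range(n_populations):
                for cl in range(clones_per_population):
                    for rep in range(n_replicates):
                        od = (
                            baseline[assay]
                            + sign * effect.od_effect
                            + rng.normal(0.0, sd)
                        )
                        rows.append(
                            {
                                "history": history,
                                "assay_salinity": assay,
                                "population": f"{pop + 1}{history[0].upper()}",
                                "clone": f"{pop + 1}{cl + 1}{history[0].upper()}",
                                "replicate": rep,
                                "od600": max(od, 0.0),
                            }
                        )
    return pd.DataFrame(rows)


def make_motility_table(
    effect: EffectSpec | None = None,
    n_clones_per_group: int = 6,
    n_replicates: int = 3,
    seed: int = 0,
    noise: bool = True,
) -> pd.DataFrame:
    """Swarming/swimming halo table; mutants shifted on swarming only.

    Genotype groups: ``mutant`` (aerotaxis-regulator mutants from
    control-salinity lines), ``wildtype`` (high-salinity lines) and
    ``ancestor``. Columns: clone_id, genotype, assay, replicate, halo_mm.
    """
    effect = effect or EffectSpec()
    rng = np.random.default_rng(seed)
    base = {"swarming": 22.0, "swimming": 30.0}
    shift = {"swarming": effect.motility_shift, "swimming": effect.swim_shift}
    sd = effect.motility_noise if noise else 0.0
    rows = []
    for assay in ("swarming", "swimming"):
        for genotype, n_clones, reps in (
            ("ancestor", 1, 6),
            ("mutant", n_clones_per_group, n_replicates),
            ("wildtype", n_clones_per_group, n_replicates),
        ):
            for cl in range(n_clones):
                for rep in range(reps):
                    halo = base[assay] + rng.normal(0.0, sd)
                    if genotype == "mutant":
                        halo += shift[assay]
                    rows.append(
                        {
                            "clone_id": f"{genotype}{cl + 1}",
                            "genotype": genotype,
                            "assay": assay,
                            "replicate": rep,
                            "halo_mm": max(halo, 0.0),
                        }
                    )
    return pd.DataFrame(rows)
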