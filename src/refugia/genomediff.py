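"""Post-variant-calling pipeline over breseq-style GenomeDiff (GD) files.

The GD dialect handled here covers the three mutation line types the study's
retained set contains — SNP, DEL, INS — as tab-separated records

    SNP <id> <parent-ids> <seq_id> <position> <new_seq> [key=value ...]
    DEL <id> <parent-ids> <seq_id> <position> <size>    [key=value ...]
    INS <id> <parent-ids> <seq_id> <position> <new_seq> [key=value ...]

with the standard ``gene_name=`` and ``snp_type=`` annotations plus an
``evidence=`` grade (consensus/marginal/unassigned). Coordinates are 1-based
inclusive. Other line types (MOB, AMP, evidence lines, ...) are skipped with
a warning.

The pipeline mirrors the study's post-processing: mutations found in any
ancestral clone — whatever their evidence grade — are pooled and subtracted
from the evolved dataset; the retained set is summarized as a mutation
spectrum, per-clone counts, per-treatment unique-locus counts, a binary
population x locus incidence matrix, and treatment-specific parallel loci
(hit in >1 population of one treatment and 0 of the other).

Mutation identity for pooling/subtraction is the tuple
``(seq_id, position, mutation_class, allele_detail)``: breseq's
mutation-level semantics, so near-miss coordinates are never merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutationRecord",
    "MutationMatrix",
    "SpectrumSummary",
    "GDParseError",
    "MUTATION_CLASSES",
    "SNP_EFFECTS",
    "parse_gd",
    "write_gd",
    "mutation_key",
    "pool_ancestral",
    "subtract_ancestral",
    "spectrum",
    "per_clone_counts",
    "unique_loci",
    "build_matrix",
    "parallel_loci",
    "load_dataset",
    "run_pipeline",
]

MUTATION_CLASSES = ("SNP", "deletion", "insertion")
SNP_EFFECTS = ("nonsynonymous", "synonymous", "intergenic", "nonsense",
               "not_applicable")
EVIDENCE_GRADES = ("consensus", "marginal", "unassigned")
TREATMENTS = ("control", "high")

_GD_TYPE_TO_CLASS = {"SNP": "SNP", "DEL": "deletion", "INS": "insertion"}
_CLASS_TO_GD_TYPE = {v: k for k, v in _GD_TYPE_TO_CLASS.items()}

# Loci counted in per-treatment spectra: those disrupted by coding-altering
# mutations. Synonymous and intergenic SNPs are excluded by default.
_LOCUS_EFFECTS = ("nonsynonymous", "nonsense", "not_applicable")


class GDParseError(ValueError):
    """Malformed GenomeDiff content; message names the offending line."""


@dataclass(frozen=True)
class MutationRecord:
    """One mutation called in one clone."""

    seq_id: str
    position: int
    mutation_class: str
    allele_detail: str
    locus: str = ""
    snp_effect: str = "not_applicable"
    evidence: str = "consensus"
    clone_id: str = ""
    population_id: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based coordinates)")
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValueError(f"mutation_class must be one of {MUTATION_CLASSES}")
        if self.snp_effect not in SNP_EFFECTS:
            raise ValueError(f"snp_effect must be one of {SNP_EFFECTS}")
        if self.mutation_class != "SNP" and self.snp_effect != "not_applicable":
            raise ValueError("snp_effect applies to SNPs only")
        if self.evidence not in EVIDENCE_GRADES:
            raise ValueError(f"evidence must be one of {EVIDENCE_GRADES}")


def mutation_key(rec: MutationRecord) -> tuple[str, int, str, str]:
    """Identity key used for pooling and subtraction."""
    return (rec.seq_id, rec.position, rec.mutation_class, rec.allele_detail)


def _parse_kv(fields: Sequence[str], lineno: int) -> dict[str, str]:
    kv = {}
    for f in fields:
        if "=" not in f:
            raise GDParseError(f"line {lineno}: expected key=value field, got {f!r}")
        k, _, v = f.partition("=")
        kv[k] = v
    return kv


def parse_gd(path: str | Path, clone_id: str = "") -> list[MutationRecord]:
    """Parse SNP/DEL/INS mutation lines from a GenomeDiff file.

    The file must begin with a ``#=GENOME_DIFF`` version header. Unknown
    line types are skipped with a warning. Raises :class:`GDParseError` on
    a missing header or malformed mandatory columns.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#=GENOME_DIFF"):
        raise GDParseError(f"{path}: missing #=GENOME_DIFF version header")
    records: list[MutationRecord] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        gd_type = fields[0]
        if gd_type not in _GD_TYPE_TO_CLASS:
            warnings.warn(
                f"{path.name} line {lineno}: skipping unsupported line type "
                f"{gd_type!r}",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        if len(fields) < 6:
            raise GDParseError(
                f"{path.name} line {lineno}: {gd_type} line needs at least 6 columns"
            )
        seq_id = fields[3]
        try:
            position = int(fields[4])
        except ValueError as exc:
            raise GDParseError(
                f"{path.name} line {lineno}: position {fields[4]!r} is not an integer"
            ) from exc
        type_field = fields[5]
        kv = _parse_kv(fields[6:], lineno)
        mutation_class = _GD_TYPE_TO_CLASS[gd_type]
        if mutation_class == "deletion":
            try:
                size = int(type_field)
            except ValueError as exc:
                raise GDParseError(
                    f"{path.name} line {lineno}: DEL size {type_field!r} is not an "
                    "integer"
                ) from exc
            allele_detail = f"del:{size}"
            snp_effect = "not_applicable"
        else:
            allele_detail = type_field
            snp_effect = (
                kv.get("snp_type", "not_applicable")
                if mutation_class == "SNP"
                else "not_applicable"
            )
            if snp_effect not in SNP_EFFECTS:
                raise GDParseError(
                    f"{path.name} line {lineno}: unknown snp_type {snp_effect!r}"
                )
        records.append(
            MutationRecord(
                seq_id=seq_id,
                position=position,
                mutation_class=mutation_class,
                allele_detail=allele_detail,
                locus=kv.get("gene_name", ""),
                snp_effect=snp_effect,
                evidence=kv.get("evidence", "consensus"),
                clone_id=clone_id,
            )
        )
    return records


def write_gd(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records back to the GD dialect (round-trips with parse_gd)."""
    lines = ["#=GENOME_DIFF\t1.0"]
    for i, rec in enumerate(records, start=1):
        gd_type = _CLASS_TO_GD_TYPE[rec.mutation_class]
        if rec.mutation_class == "deletion":
            type_field = rec.allele_detail.removeprefix("del:")
        else:
            type_field = rec.allele_detail
        fields = [gd_type, str(i), ".", rec.seq_id, str(rec.position), type_field]
        if rec.locus:
            fields.append(f"gene_name={rec.locus}")
        if rec.mutation_class == "SNP":
            fields.append(f"snp_type={rec.snp_effect}")
        if rec.evidence != "consensus":
            fields.append(f"evidence={rec.evidence}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def pool_ancestral(
    ancestors: Iterable[str | Path | Sequence[MutationRecord]],
) -> set[tuple]:
    """Union of mutation identity keys across ancestor clones.

    Accepts GD paths or already-parsed record lists. All entries are
    included regardless of evidence grade — marginal and unassigned calls
    are pooled too, since the goal is to mask the laboratory strain's
    divergence from the reference and mapping artefacts.
    """
    ancestors = list(ancestors)
    if not ancestors:
        raise ValueError("at least one ancestor is required")
    pooled: set[tuple] = set()
    for anc in ancestors:
        records = (
            parse_gd(anc) if isinstance(anc, (str, Path)) else list(anc)
        )
        pooled.update(mutation_key(r) for r in records)
    return pooled


def subtract_ancestral(
    records: Iterable[MutationRecord], pooled: set[tuple]
) -> list[MutationRecord]:
    """Drop every record whose identity key is in the pooled ancestral set."""
    return [r for r in records if mutation_key(r) not in pooled]


@dataclass(frozen=True)
class SpectrumSummary:
    """Unique-mutation counts and one-decimal percentages by class/effect."""

    total: int
    class_counts: dict
    class_percent: dict
    effect_counts: dict
    effect_percent: dict


def _round1(x: float) -> float:
    """Round half away from zero to one decimal place."""
    return np.floor(x * 10.0 + 0.5) / 10.0 if x >= 0 else -np.floor(-x * 10.0 + 0.5) / 10.0


def spectrum(records: Iterable[MutationRecord]) -> SpectrumSummary:
    """Mutation spectrum over *unique* retained mutations.

    The same mutation observed in several clones counts once. Percentages
    are counts/total rounded half away from zero to one decimal; the raw
    counts are carried alongside because one-decimal percentages of small
    denominators are lossy.
    """
    seen: dict[tuple, MutationRecord] = {}
    for r in records:
        seen.setdefault(mutation_key(r), r)
    uniq = list(seen.values())
    total = len(uniq)
    class_counts = {c: 0 for c in MUTATION_CLASSES}
    effect_counts = {e: 0 for e in SNP_EFFECTS if e != "not_applicable"}
    for r in uniq:
        class_counts[r.mutation_class] += 1
        if r.mutation_class == "SNP":
            effect_counts[r.snp_effect] += 1
    pct = lambda c: _round1(100.0 * c / total) if total else 0.0
    return SpectrumSummary(
        total=total,
        class_counts=class_counts,
        class_percent={k: pct(v) for k, v in class_counts.items()},
        effect_counts=effect_counts,
        effect_percent={k: pct(v) for k, v in effect_counts.items()},
    )


def per_clone_counts(
    records: Iterable[MutationRecord], clone_ids: Sequence[str]
) -> pd.DataFrame:
    """Retained-mutation count per clone, including zero-mutation clones.

    Returns a frame with columns ``clone_id, count`` and attrs
    ``median``/``min``/``max`` over the full roster.
    """
    counts = {c: 0 for c in clone_ids}
    for r in records:
        if r.clone_id not in counts:
            counts[r.clone_id] = 0
        counts[r.clone_id] += 1
    out = pd.DataFrame(
        {"clone_id": list(counts), "count": list(counts.values())}
    ).sort_values("clone_id", ignore_index=True)
    out.attrs["median"] = float(out["count"].median())
    out.attrs["min"] = int(out["count"].min())
    out.attrs["max"] = int(out["count"].max())
    return out


def _locus_relevant(rec: MutationRecord, include_all: bool) -> bool:
    if not rec.locus:
        return False
    if include_all:
        return True
    return rec.snp_effect in _LOCUS_EFFECTS


def unique_loci(
    records: Iterable[MutationRecord],
    treatment: str | None = None,
    include_all: bool = False,
) -> set[str]:
    """Distinct loci hit by retained mutations, optionally per treatment.

    By default only coding-disrupting records count (non-synonymous and
    nonsense SNPs, insertions, deletions); pass ``include_all=True`` to
    keep synonymous and intergenic records too.
    """
    if treatment is not None and treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    return {
        r.locus
        for r in records
        if _locus_relevant(r, include_all)
        and (treatment is None or r.treatment == treatment)
    }


@dataclass(frozen=True)
class MutationMatrix:
    """Binary population x locus incidence with treatment labels."""

    incidence: pd.DataFrame  # index: population_id, columns: loci (sorted)
    treatments: pd.Series  # index: population_id -> treatment label


def build_matrix(
    records: Iterable[MutationRecord],
    populations: Sequence[tuple[str, str]] | None = None,
    include_all: bool = False,
) -> MutationMatrix:
    """Population x locus presence/absence matrix over retained records.

    ``populations`` is an optional roster of ``(population_id, treatment)``
    pairs so populations without retained mutations appear as all-zero
    rows. Column order is lexicographic (deterministic).
    """
    records = list(records)
    pop_treat: dict[str, str] = dict(populations or [])
    for r in records:
        if r.population_id and r.population_id not in pop_treat:
            pop_treat[r.population_id] = r.treatment
    pops = sorted(pop_treat)
    loci = sorted({r.locus for r in records if _locus_relevant(r, include_all)})
    inc = pd.DataFrame(0, index=pops, columns=loci, dtype=np.int8)
    for r in records:
        if _locus_relevant(r, include_all) and r.population_id:
            inc.loc[r.population_id, r.locus] = 1
    treatments = pd.Series({p: pop_treat[p] for p in pops}, name="treatment")
    return MutationMatrix(incidence=inc, treatments=treatments)


def parallel_loci(matrix: MutationMatrix) -> pd.DataFrame:
    """Treatment-specific parallel loci.

    A locus is flagged for treatment T when it is mutated in more than one
    population of T and in zero populations of the other treatment — the
    signature of treatment-specific parallel (and hence likely adaptive)
    evolution. Requires at least one population per treatment.
    """
    treat = matrix.treatments
    for t in TREATMENTS:
        if not (treat == t).any():
            raise ValueError(f"no populations with treatment {t!r}")
    rows = []
    for locus in matrix.incidence.columns:
        col = matrix.incidence[locus]
        hits = {t: int(col[treat == t].sum()) for t in TREATMENTS}
        for t in TREATMENTS:
            other = "high" if t == "control" else "control"
            if hits[t] >= 2 and hits[other] == 0:
                rows.append(
                    {"locus": locus, "treatment": t, "n_populations": hits[t]}
                )
    return pd.DataFrame(rows, columns=["locus", "treatment", "n_populations"])


# --------------------------------------------------------------------------
# Dataset assembly and the end-to-end pipeline
# --------------------------------------------------------------------------

def load_dataset(
    sample_sheet: str | Path, gd_dir: str | Path
) -> tuple[list[MutationRecord], list[MutationRecord], pd.DataFrame]:
    """Read a sample sheet and its GD files.

    The sheet must have columns ``clone_id, population_id, treatment, role``
    with role in {ancestor, evolved}; each clone_id maps to
    ``<gd_dir>/<clone_id>.gd``. Returns (ancestor records, evolved records,
    roster frame). Evolved records are annotated with population/treatment.
    """
    sheet = pd.read_csv(sample_sheet)
    required = {"clone_id", "population_id", "treatment", "role"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet is missing columns: {sorted(missing)}")
    gd_dir = Path(gd_dir)
    ancestors: list[MutationRecord] = []
    evolved: list[MutationRecord] = []
    for row in sheet.itertuples(index=False):
        recs = parse_gd(gd_dir / f"{row.clone_id}.gd", clone_id=str(row.clone_id))
        annotated = [
            replace(
                r,
                population_id=str(row.population_id),
                treatment=str(row.treatment) if row.role == "evolved" else "",
            )
            for r in recs
        ]
        (ancestors if row.role == "ancestor" else evolved).extend(annotated)
    return ancestors, evolved, sheet


def run_pipeline(sample_sheet: str | Path, gd_dir: str | Path) -> dict:
    """Full post-processing pipeline on a GD dataset.

    Pools ancestral mutations, subtracts them from the evolved dataset, and
    returns every downstream summary in one dict: pooled size, evolved
    unique size, retained records/size, spectrum, per-clone counts, unique
    loci per treatment, the incidence matrix and parallel loci.
    """
    ancestors, evolved, sheet = load_dataset(sample_sheet, gd_dir)
    pooled = pool_ancestral([ancestors])
    retained = subtract_ancestral(evolved, pooled)
    evolved_sheet = sheet[sheet["role"] == "evolved"]
    clone_ids = [str(c) for c in evolved_sheet["clone_id"]]
    populations = sorted(
        {
            (str(r.population_id), str(r.treatment))
            for r in evolved_sheet.itertuples(index=False)
        }
    )
    matrix = build_matrix(retained, populations=populations)
    return {
        "pooled_ancestral": pooled,
        "n_pooled": len(pooled),
        "n_evolved_unique": len({mutation_key(r) for r in evolved}),
        "retained": retained,
        "n_retained_unique": len({mutation_key(r) for r in retained}),
        "spectrum": spectrum(retained),
        "per_clone": per_clone_counts(retained, clone_ids),
        "unique_loci": {
            t: unique_loci(retained, treatment=t) for t in TREATMENTS
        },
        "matrix": matrix,
        "parallel": parallel_loci(matrix),
    }
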