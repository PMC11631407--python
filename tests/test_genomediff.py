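"""GenomeDiff parsing and post-processing pipeline tests."""

import numpy as np
import pandas as pd
import pytest

from refugia.genomediff import (
    GDParseError,
    MutationMatrix,
    MutationRecord,
    build_matrix,
    mutation_key,
    parallel_loci,
    parse_gd,
    per_clone_counts,
    pool_ancestral,
    run_pipeline,
    spectrum,
    subtract_ancestral,
    unique_loci,
    write_gd,
)

HEADER = "#=GENOME_DIFF\t1.0\n"


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


def rec(pos=100, cls="SNP", allele="A", locus="PFLU_0001",
        effect=None, clone="c1", pop="1C", treatment="control"):
    return MutationRecord(
        seq_id="AM181176", position=pos, mutation_class=cls,
        allele_detail=allele, locus=locus,
        snp_effect=effect or ("nonsynonymous" if cls == "SNP" else "not_applicable"),
        clone_id=clone, population_id=pop, treatment=treatment,
    )


class TestParser:
    def test_missing_header_rejected(self, tmp_path):
        path = write(tmp_path, "bad.gd", "SNP\t1\t.\tchr\t5\tA\n")
        with pytest.raises(GDParseError, match="header"):
            parse_gd(path)

    def test_header_only_gives_empty_list(self, tmp_path):
        assert parse_gd(write(tmp_path, "empty.gd", HEADER)) == []

    def test_snp_line_field_mapping(self, tmp_path):
        line = ("SNP\t1\t23\tAM181176\t5013904\tT\t"
                "gene_name=PFLU_4551\tsnp_type=nonsynonymous\n")
        records = parse_gd(write(tmp_path, "one.gd", HEADER + line), clone_id="11C")
        assert len(records) == 1
        r = records[0]
        assert r.mutation_class == "SNP"
        assert r.position == 5013904
        assert r.snp_effect == "nonsynonymous"
        assert r.locus == "PFLU_4551"
        assert r.allele_detail == "T"
        assert r.evidence == "consensus"
        assert r.clone_id == "11C"

    def test_del_and_ins_lines(self, tmp_path):
        text = HEADER + (
            "DEL\t1\t.\tAM181176\t1000\t350\tgene_name=PFLU_0100\n"
            "INS\t2\t.\tAM181176\t2000\tCCG\tgene_name=PFLU_0200\n"
        )
        records = parse_gd(write(tmp_path, "two.gd", text))
        assert records[0].mutation_class == "deletion"
        assert records[0].allele_detail == "del:350"
        assert records[1].mutation_class == "insertion"
        assert records[1].allele_detail == "CCG"
        assert all(r.snp_effect == "not_applicable" for r in records)

    def test_unknown_line_types_skipped_with_warning(self, tmp_path):
        text = HEADER + (
            "MOB\t1\t.\tAM181176\t500\tIS3\t1\t5\n"
            "RA\t2\t.\tAM181176\t600\t0\tA\tG\n"
            "SNP\t3\t.\tAM181176\t700\tG\n"
        )
        with pytest.warns(RuntimeWarning):
            records = parse_gd(write(tmp_path, "mixed.gd", text))
        assert len(records) == 1

    def test_malformed_position_names_line(self, tmp_path):
        path = write(tmp_path, "bad.gd", HEADER + "SNP\t1\t.\tchr\tXYZ\tA\n")
        with pytest.raises(GDParseError, match="line 2"):
            parse_gd(path)

    def test_round_trip(self, tmp_path):
        originals = [
            rec(pos=10, cls="SNP", allele="G", effect="synonymous"),
            rec(pos=20, cls="deletion", allele="del:3"),
            rec(pos=30, cls="insertion", allele="TTA"),
        ]
        path = tmp_path / "rt.gd"
        write_gd(originals, path)
        parsed = parse_gd(path)
        for orig, back in zip(originals, parsed):
            assert mutation_key(orig) == mutation_key(back)
            assert orig.locus == back.locus
            assert orig.snp_effect == back.snp_effect
            assert orig.evidence == back.evidence


class TestPoolingAndSubtraction:
    def test_empty_ancestor_gives_empty_pool(self, tmp_path):
        path = write(tmp_path, "anc.gd", HEADER)
        assert pool_ancestral([path]) == set()

    def test_union_of_shared_and_private(self):
        shared = rec(pos=1)
        pool = pool_ancestral([[shared, rec(pos=2)], [shared, rec(pos=3)]])
        assert len(pool) == 3

    def test_marginal_evidence_is_pooled_too(self):
        marginal = MutationRecord(
            seq_id="AM181176", position=7, mutation_class="SNP",
            allele_detail="A", evidence="marginal",
        )
        assert mutation_key(marginal) in pool_ancestral([[marginal]])

    def test_no_ancestors_rejected(self):
        with pytest.raises(ValueError):
            pool_ancestral([])

    def test_empty_pool_is_identity(self):
        records = [rec(pos=i) for i in (1, 2, 3)]
        assert subtract_ancestral(records, set()) == records

    def test_removes_every_occurrence_across_clones(self):
        shared_key_recs = [rec(pos=5, clone=c) for c in ("c1", "c2", "c3")]
        other = rec(pos=9)
        pooled = {mutation_key(shared_key_recs[0])}
        retained = subtract_ancestral(shared_key_recs + [other], pooled)
        assert retained == [other]

    def test_idempotent_and_order_independent(self):
        ancestors = [[rec(pos=1), rec(pos=2)], [rec(pos=3)]]
        records = [rec(pos=1), rec(pos=4)]
        p_forward = pool_ancestral(ancestors)
        p_reverse = pool_ancestral(ancestors[::-1])
        assert p_forward == p_reverse
        once = subtract_ancestral(records, p_forward)
        assert subtract_ancestral(once, p_forward) == once


class TestSpectrum:
    def test_single_snp_is_all_snp(self):
        sp = spectrum([rec()])
        assert sp.class_percent["SNP"] == 100.0
        assert sp.total == 1

    def test_even_split(self):
        records = [
            rec(pos=1, cls="deletion", allele="del:1"),
            rec(pos=2, cls="deletion", allele="del:2"),
            rec(pos=3, cls="insertion", allele="A"),
            rec(pos=4, cls="insertion", allele="T"),
        ]
        sp = spectrum(records)
        assert sp.class_percent == {"SNP": 0.0, "deletion": 50.0,
                                    "insertion": 50.0}

    def test_duplicates_across_clones_count_once(self):
        twice = [rec(pos=1, clone="c1"), rec(pos=1, clone="c2")]
        assert spectrum(twice).total == 1

    def test_percentages_sum_to_100(self, gd_pipeline):
        sp = gd_pipeline["spectrum"]
        assert sum(sp.class_percent.values()) == pytest.approx(100.0, abs=0.1)


class TestPerCloneCounts:
    def test_zero_mutation_clones_counted(self):
        out = per_clone_counts([], ["a", "b", "c"])
        assert out["count"].tolist() == [0, 0, 0]
        assert out.attrs["median"] == 0.0

    def test_median_and_range(self):
        records = [rec(clone="b"), rec(pos=2, clone="c"),
                   rec(pos=3, clone="d"), rec(pos=4, clone="d")]
        out = per_clone_counts(records, ["a", "b", "c", "d"])
        assert out.attrs["median"] == 1.0
        assert (out.attrs["min"], out.attrs["max"]) == (0, 2)


class TestLociAndMatrix:
    def test_empty_records_give_no_loci(self):
        assert unique_loci([]) == set()

    def test_set_semantics(self):
        records = [rec(pos=i, locus="PFLU_0001") for i in (1, 2, 3)]
        records.append(rec(pos=9, cls="deletion", allele="del:5",
                           locus="PFLU_0002"))
        assert len(unique_loci(records)) == 2

    def test_synonymous_and_intergenic_excluded_by_default(self):
        records = [
            rec(pos=1, effect="synonymous"),
            rec(pos=2, effect="intergenic", locus="PFLU_0001/PFLU_0002"),
            rec(pos=3, effect="nonsense", locus="PFLU_0003"),
        ]
        assert unique_loci(records) == {"PFLU_0003"}
        assert len(unique_loci(records, include_all=True)) == 3

    def test_unknown_treatment_rejected(self):
        with pytest.raises(ValueError):
            unique_loci([rec()], treatment="briny")

    def test_population_level_collapse(self):
        records = [rec(pos=1, clone="c1"), rec(pos=2, clone="c2")]
        m = build_matrix(records)
        assert m.incidence.loc["1C", "PFLU_0001"] == 1
        assert m.incidence.to_numpy().sum() == 1

    def test_empty_matrix(self):
        m = build_matrix([], populations=[("1C", "control"), ("1H", "high")])
        assert m.incidence.shape == (2, 0)


class TestParallelLoci:
    def make_matrix(self, columns):
        pops = [("1C", "control"), ("2C", "control"),
                ("1H", "high"), ("2H", "high")]
        inc = pd.DataFrame(columns, index=[p for p, _ in pops])
        treatments = pd.Series(dict(pops), name="treatment")
        return MutationMatrix(incidence=inc, treatments=treatments)

    def test_single_population_not_flagged(self):
        m = self.make_matrix({"locusA": [1, 0, 0, 0]})
        assert parallel_loci(m).empty

    def test_shared_across_treatments_not_flagged(self):
        m = self.make_matrix({"locusA": [1, 1, 1, 1]})
        assert parallel_loci(m).empty

    def test_exclusive_parallel_locus_flagged(self):
        m = self.make_matrix({"locusA": [1, 1, 0, 0]})
        out = parallel_loci(m)
        assert out["locus"].tolist() == ["locusA"]
        assert out["treatment"].iloc[0] == "control"
        assert out["n_populations"].iloc[0] == 2

    def test_invariant_to_row_permutation(self):
        rng = np.random.default_rng(0)
        cols = {f"L{i}": rng.integers(0, 2, size=4).tolist() for i in range(6)}
        m = self.make_matrix(cols)
        perm = rng.permutation(m.incidence.index)
        m_perm = MutationMatrix(
            incidence=m.incidence.loc[perm],
            treatments=m.treatments.loc[perm],
        )
        a = parallel_loci(m).sort_values("locus").reset_index(drop=True)
        b = parallel_loci(m_perm).sort_values("locus").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_treatment_rejected(self):
        inc = pd.DataFrame({"L": [1, 1]}, index=["1C", "2C"])
        treatments = pd.Series({"1C": "control", "2C": "control"})
        with pytest.raises(ValueError):
            parallel_loci(MutationMatrix(incidence=inc, treatments=treatments))


class TestPipelineOnFixture:
    def test_record_counts_match_manifest(self, gd_fixture):
        d, manifest = gd_fixture
        for clone_id, expected in manifest.per_file_counts.items():
            assert len(parse_gd(d / f"{clone_id}.gd")) == expected

    def test_composition_reproduces_all_published_counts(self, gd_pipeline):
        res = gd_pipeline
        assert res["n_pooled"] == 43
        assert res["n_evolved_unique"] == 78
        assert res["n_retained_unique"] == 35
        sp = res["spectrum"]
        assert (sp.class_percent["deletion"], sp.class_percent["insertion"],
                sp.class_percent["SNP"]) == (31.4, 11.4, 57.1)
        assert len(res["unique_loci"]["control"]) == 5
        assert len(res["unique_loci"]["high"]) == 16
        par = res["parallel"]
        assert len(par) == 1 and par["locus"].iloc[0] == "PFLU_4551"

    def test_parallel_locus_column_pattern(self, gd_pipeline):
        m = gd_pipeline["matrix"]
        col = m.incidence["PFLU_4551"]
        assert col[m.treatments == "control"].sum() == 5
        assert col[m.treatments == "high"].sum() == 0
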