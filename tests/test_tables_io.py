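"""Table plumbing: parsing, lineage resolution, table algebra, file I/O."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metatracker.errors import MetatrackerError, ParseError
from metatracker.tables_io import (
    Domain,
    FeatureTable,
    align_mapping,
    collapse_by_env,
    filter_min_depth,
    merge_counts,
    parse_classifier_report,
    parse_lineage_string,
    rarefy,
    read_feature_table,
    read_mapping,
    resolve_domain,
    split_by_domain,
    write_classifier_report,
    write_feature_table,
)

PAPER_LINEAGE = (
    "sk:Bacteria;p:Proteobacteria;c:Gammaproteobacteria;"
    "o:Enterobacterales;f: Enterobacteriaceae;g:Salmonella"
)


class TestClassifierReport:
    def test_name_dialect_maps_fields_directly(self):
        recs = parse_classifier_report(io.StringIO("Salmonella\t42\n"), "s1")
        assert recs == [("s1", "Salmonella", 42)]

    def test_lineage_dialect_keeps_full_string(self):
        recs = parse_classifier_report(
            io.StringIO(f"{PAPER_LINEAGE}\t7\n"), "s1", dialect="lineage"
        )
        assert recs == [("s1", PAPER_LINEAGE, 7)]

    def test_zero_count_records_dropped(self):
        recs = parse_classifier_report(
            io.StringIO("A\t3\nB\t0\nC\t1\n"), "s1"
        )
        assert [r[1] for r in recs] == ["A", "C"]

    @pytest.mark.parametrize("bad,msg", [
        ("A\tx\n", "line 1"),
        ("ok\t1\nA\tB\tC\n", "line 2"),
        ("A\t-3\n", "line 1"),
    ])
    def test_malformed_line_names_line_number(self, bad, msg):
        with pytest.raises(ParseError, match=msg):
            parse_classifier_report(io.StringIO(bad), "s1")

    def test_unknown_dialect_rejected(self):
        with pytest.raises(ParseError, match="dialect"):
            parse_classifier_report(io.StringIO("A\t1\n"), "s1", dialect="csv")

    def test_three_taxon_roundtrip(self):
        recs = parse_classifier_report(
            io.StringIO("A\t3\nB\t12\nC\t1\n"), "s1"
        )
        buf = io.StringIO()
        write_classifier_report(recs, buf)
        buf.seek(0)
        assert parse_classifier_report(buf, "s1") == recs


class TestLineageParsing:
    def test_full_lineage_resolves_genus_and_domain(self):
        rec = parse_lineage_string(PAPER_LINEAGE)
        assert rec.domain is Domain.BACTERIA
        assert rec.rank("g") == "Salmonella"
        assert not rec.incomplete

    def test_empty_string_is_unresolved(self):
        assert parse_lineage_string("").domain is Domain.UNRESOLVED

    def test_partial_lineage_still_maps_superkingdom(self):
        rec = parse_lineage_string("sk:Archaea;g:Methanobrevibacter")
        assert rec.domain is Domain.ARCHAEA
        assert not rec.incomplete

    def test_token_without_colon_flags_incomplete(self):
        rec = parse_lineage_string("sk:Bacteria;Proteobacteria")
        assert rec.incomplete
        assert rec.domain is Domain.BACTERIA  # sk still parseable

    def test_unrecognized_superkingdom_is_unresolved(self):
        assert parse_lineage_string("sk:Klingon;g:Worf").domain is Domain.UNRESOLVED


class TestResolveDomain:
    def test_bare_name_via_map(self):
        assert resolve_domain("Salmonella", {"Salmonella": PAPER_LINEAGE}) \
            is Domain.BACTERIA

    def test_lookup_miss_is_unresolved_not_error(self):
        assert resolve_domain("NotATaxon", {}) is Domain.UNRESOLVED

    def test_incomplete_lineage_excluded_from_analysis_domains(self):
        # malformed token => treated as unresolved even though sk parses
        assert resolve_domain("X", {"X": "sk:Bacteria;Proteobacteria"}) \
            is Domain.UNRESOLVED

    def test_every_fixture_map_key_resolves_as_written(self, fixture_lineage_map):
        for name, lineage in fixture_lineage_map.items():
            expected = Domain(lineage.split(";")[0].split(":")[1])
            assert resolve_domain(name, fixture_lineage_map) is expected


class TestMergeCounts:
    def test_two_samples_two_taxa(self):
        table = merge_counts([("a", "t1", 3), ("b", "t1", 4), ("b", "t2", 1)])
        assert table.data.shape == (2, 2)
        assert table.sample_sums().to_dict() == {"a": 3, "b": 5}
        assert table.data.loc["t2", "a"] == 0

    def test_single_record(self):
        table = merge_counts([("s", "t", 9)])
        assert table.data.shape == (1, 1)
        assert table.total() == 9

    def test_duplicates_summed(self):
        table = merge_counts([("a", "t1", 3), ("a", "t1", 4)])
        assert table.data.loc["t1", "a"] == 7

    def test_grand_total_conserved_on_random_records(self, rng):
        records = [
            (f"s{rng.integers(20)}", f"t{rng.integers(40)}", int(rng.integers(1, 50)))
            for _ in range(500)
        ]
        table = merge_counts(records)
        assert table.total() == sum(c for _, _, c in records)


class TestSplitByDomain:
    def test_one_row_per_domain(self, fixture_lineage_map):
        table = merge_counts([("s1", "genus00", 5), ("s1", "genus01", 2)])
        buckets = split_by_domain(table, fixture_lineage_map)
        assert buckets[Domain.BACTERIA].n_taxa == 1
        assert buckets[Domain.ARCHAEA].n_taxa == 1
        assert buckets[Domain.UNRESOLVED].n_taxa == 0

    def test_all_unresolved_goes_to_bucket(self):
        table = merge_counts([("s1", "mystery1", 5), ("s2", "mystery2", 2)])
        buckets = split_by_domain(table, {})
        assert buckets[Domain.UNRESOLVED].total() == 7
        assert all(buckets[d].n_taxa == 0 for d in Domain if d != Domain.UNRESOLVED)

    def test_partition_is_disjoint_exhaustive_and_conserving(
        self, rng, fixture_lineage_map
    ):
        records = [
            (f"s{rng.integers(6)}", f"genus{rng.integers(60):02d}",
             int(rng.integers(1, 30)))
            for _ in range(300)
        ]  # genus50..59 miss the 50-entry map -> unresolved
        table = merge_counts(records)
        buckets = split_by_domain(table, fixture_lineage_map)
        all_rows = [t for b in buckets.values() for t in b.taxon_ids]
        assert sorted(all_rows) == sorted(table.taxon_ids)
        combined = sum(
            b.data.reindex(index=table.taxon_ids, columns=table.sample_ids,
                           fill_value=0)
            for b in buckets.values()
        )
        pd.testing.assert_frame_equal(combined, table.data)


class TestDepthFilterAndRarefaction:
    def test_minimum_count_boundary(self):
        table = merge_counts([("low", "t1", 999), ("ok", "t1", 1000)])
        filtered, removed = filter_min_depth(table, 1000)
        assert removed == ["low"]
        assert filtered.sample_ids == ["ok"]

    def test_empty_table(self):
        table = FeatureTable(pd.DataFrame(index=pd.Index([], name="taxon_id")))
        filtered, removed = filter_min_depth(table, 1000)
        assert removed == [] and filtered.n_samples == 0

    def test_rarefy_identity_at_exact_depth(self):
        table = merge_counts([("s", "t1", 600), ("s", "t2", 400)])
        out = rarefy(table, depth=1000, seed=1)
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_rarefy_single_taxon(self):
        table = merge_counts([("s", "t1", 5000)])
        assert rarefy(table, 1000, seed=1).data.loc["t1", "s"] == 1000

    def test_rarefy_columns_sum_to_depth_and_seed_determinism(self, rng):
        counts = rng.integers(0, 200, size=(30, 8))
        counts[0] += 2000  # ensure depth
        table = FeatureTable(pd.DataFrame(
            counts, index=[f"t{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(8)]))
        a = rarefy(table, 1000, seed=9)
        b = rarefy(table, 1000, seed=9)
        c = rarefy(table, 1000, seed=10)
        assert (a.sample_sums() == 1000).all()
        pd.testing.assert_frame_equal(a.data, b.data)
        assert not a.data.equals(c.data)

    def test_rarefy_invariant_to_sample_order(self):
        table = merge_counts(
            [("s1", "t1", 900), ("s1", "t2", 600), ("s2", "t1", 1500)]
        )
        flipped = FeatureTable(table.data[["s2", "s1"]])
        a = rarefy(table, 1000, seed=4).data
        b = rarefy(flipped, 1000, seed=4).data
        pd.testing.assert_frame_equal(a, b[a.columns])

    def test_rarefy_below_depth_names_sample(self):
        table = merge_counts([("shallow", "t1", 10)])
        with pytest.raises(MetatrackerError, match="shallow"):
            rarefy(table, 1000)

    def test_rarefied_mean_matches_hypergeometric_expectation(self):
        # two-taxon sample (9000, 1000); draws of 1000 without replacement
        table = merge_counts([("s", "t1", 9000), ("s", "t2", 1000)])
        draws = np.array([
            rarefy(table, 1000, seed=k).data.loc["t2", "s"] for k in range(500)
        ])
        hg = stats.hypergeom(M=10000, n=1000, N=1000)
        se = hg.std() / np.sqrt(500)
        assert abs(draws.mean() - hg.mean()) < 3 * se


class TestCollapseByEnv:
    def test_source_samples_summed_per_env(self):
        table = merge_counts(
            [("s1", "t1", 1), ("s1", "t2", 2), ("s2", "t1", 3), ("s2", "t2", 4)]
        )
        meta = pd.DataFrame({"env": ["soil", "soil"], "role": ["source", "source"]},
                            index=["s1", "s2"])
        out = collapse_by_env(table, meta)
        assert out["soil"].tolist() == [4, 6]

    def test_single_sample_env_passthrough_and_sink_exclusion(
        self, small_table, small_metadata
    ):
        out = collapse_by_env(small_table, small_metadata)
        assert list(out.columns) == ["soil"]  # sink's env never appears
        assert out["soil"].tolist() == (
            small_table.data["s1"] + small_table.data["s2"]
        ).tolist()

    def test_grand_total_conserved_and_envs_sorted(self, rng):
        envs = ["soil", "gut", "marine"]
        records, meta_rows = [], []
        for e, env in enumerate(envs):
            for i in range(5):
                sid = f"{env}{i}"
                meta_rows.append((sid, env, "source"))
                records += [(sid, f"t{t}", int(rng.integers(1, 9)))
                            for t in range(7)]
        table = merge_counts(records)
        meta = pd.DataFrame([(e, r) for _, e, r in meta_rows],
                            index=[s for s, _, _ in meta_rows],
                            columns=["env", "role"])
        out = collapse_by_env(table, meta)
        assert list(out.columns) == sorted(envs)
        assert out.to_numpy().sum() == table.total()


class TestFileIO:
    @pytest.mark.parametrize("fmt,suffix", [("tsv", ".tsv"), ("biom", ".biom")])
    def test_feature_table_roundtrip(self, tmp_path, rng, fmt, suffix):
        table = FeatureTable(pd.DataFrame(
            rng.integers(0, 100, size=(10, 6)),
            index=[f"taxon{i}" for i in range(10)],
            columns=[f"sample{j}" for j in range(6)]))
        path = tmp_path / f"table{suffix}"
        write_feature_table(table, path, format=fmt)
        back = read_feature_table(path, format=fmt)
        pd.testing.assert_frame_equal(back.data, table.data)

    def test_mapping_roundtrip_case_insensitive_role(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("SampleID\tEnv\tSourceSink\ns1\tsoil\tSink\ns2\tgut\tSOURCE\n")
        meta = read_mapping(path)
        assert meta.loc["s1", "role"] == "sink"
        assert meta.loc["s2", "role"] == "source"

    def test_mapping_invalid_role_rejected(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("SampleID\tEnv\tSourceSink\ns1\tsoil\tboth\n")
        with pytest.raises(ParseError, match="both"):
            read_mapping(path)

    def test_mapping_missing_file_names_path(self, tmp_path):
        with pytest.raises(MetatrackerError, match="nope.tsv"):
            read_mapping(tmp_path / "nope.tsv")

    def test_align_mapping_reports_missing_samples(self, small_table):
        meta = pd.DataFrame(
            {"env": ["soil", "gut"], "role": ["source", "source"]},
            index=["s1", "ghost"])
        kept, missing = align_mapping(small_table, meta)
        assert missing == ["ghost"]
        assert list(kept.index) == ["s1"]

    def test_duplicate_taxon_ids_rejected(self):
        df = pd.DataFrame([[1], [2]], index=["t", "t"], columns=["s"])
        with pytest.raises(MetatrackerError, match="duplicate taxon"):
            FeatureTable(df)

    def test_negative_counts_rejected(self):
        df = pd.DataFrame([[-1]], index=["t"], columns=["s"])
        with pytest.raises(MetatrackerError, match="non-negative"):
            FeatureTable(df)
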