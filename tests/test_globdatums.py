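import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from datumflow import FileTree, ValidationError, datum_diff, parse_glob, partition
from tests.conftest import make_tree


class TestPatternValidation:
    @pytest.mark.parametrize("pattern", ["/", "/*", "/plates/*", "/run_*", "/a/b/c"])
    def test_valid_patterns_accepted(self, pattern):
        parse_glob(pattern)

    @pytest.mark.parametrize(
        "pattern", ["", "*", "a/*", "/**", "/a/**", "/a/", "//", "/a?", "/[ab]"]
    )
    def test_invalid_patterns_rejected(self, pattern):
        with pytest.raises(ValidationError):
            parse_glob(pattern)


class TestPartition:
    def test_slash_star_gives_one_datum_per_sample(self):
        # the per-sample scatter shape: one LC-MS run file per datum
        tree = make_tree({f"/run_{i:03d}.csv": str(i).encode() for i in range(138)})
        datums = partition(tree, "/*")
        assert len(datums) == 138
        assert [d.root for d in datums] == sorted(d.root for d in datums)

    def test_slash_gives_single_datum_with_every_file(self):
        tree = make_tree({"/a": b"1", "/d/b": b"2", "/d/c": b"3"})
        datums = partition(tree, "/")
        assert len(datums) == 1
        assert set(datums[0].files) == {"/a", "/d/b", "/d/c"}

    def test_empty_tree_yields_no_datums(self):
        assert partition(FileTree(), "/*") == []
        assert partition(FileTree(), "/") == []

    def test_directory_entry_is_one_datum_with_its_subtree(self):
        tree = make_tree({"/plate1/s1.csv": b"1", "/plate1/s2.csv": b"2", "/plate2/s3.csv": b"3"})
        datums = partition(tree, "/*")
        assert [d.root for d in datums] == ["/plate1", "/plate2"]
        assert set(datums[0].files) == {"/plate1/s1.csv", "/plate1/s2.csv"}

    def test_component_wildcard_pattern(self):
        tree = make_tree({"/plates/p1/s.csv": b"1", "/plates/p2/s.csv": b"2", "/other/x": b"3"})
        datums = partition(tree, "/plates/*")
        assert [d.root for d in datums] == ["/plates/p1", "/plates/p2"]

    def test_conservation_under_slash_star(self):
        files = {f"/s{i}.csv": str(i).encode() for i in range(7)}
        files["/dir/deep.csv"] = b"deep"
        datums = partition(make_tree(files), "/*")
        covered = [p for d in datums for p in d.files]
        assert sorted(covered) == sorted(files)  # exactly once each


class TestDatumId:
    def test_id_depends_on_content_not_commit(self):
        a = partition(make_tree({"/s.csv": b"peaks"}), "/*")[0]
        b = next(
            d for d in partition(make_tree({"/s.csv": b"peaks", "/other.csv": b"x"}), "/*")
            if d.root == "/s.csv"
        )
        assert a.root == b.root == "/s.csv"
        assert a.datum_id == b.datum_id

    def test_one_byte_change_changes_id(self):
        a = partition(make_tree({"/s.csv": b"peaks"}), "/*")[0]
        b = partition(make_tree({"/s.csv": b"peakz"}), "/*")[0]
        assert a.datum_id != b.datum_id

    def test_id_is_path_sensitive(self):
        a = partition(make_tree({"/a.csv": b"same"}), "/*")[0]
        b = partition(make_tree({"/b.csv": b"same"}), "/*")[0]
        assert a.datum_id != b.datum_id


class TestDatumDiff:
    def test_identical_trees_all_unchanged(self):
        tree = make_tree({"/a": b"1", "/b": b"2"})
        diff = datum_diff(tree, tree, "/*")
        assert len(diff.unchanged) == 2
        assert diff.changed == () and diff.removed == ()

    def test_no_old_tree_marks_everything_changed(self):
        tree = make_tree({"/a": b"1", "/b": b"2"})
        diff = datum_diff(None, tree, "/*")
        assert len(diff.changed) == 2 and diff.unchanged == ()

    def test_added_file_is_single_changed_datum(self):
        old = make_tree({"/a": b"1", "/b": b"2"})
        new = make_tree({"/a": b"1", "/b": b"2", "/c": b"3"})
        diff = datum_diff(old, new, "/*")
        assert [d.root for d in diff.changed] == ["/c"]
        assert len(diff.unchanged) == 2

    def test_deleted_file_is_removed_datum(self):
        old = make_tree({"/a": b"1", "/b": b"2", "/c": b"3"})
        new = make_tree({"/a": b"1", "/b": b"2"})
        diff = datum_diff(old, new, "/*")
        assert len(diff.unchanged) == 2
        assert diff.removed == ("/c",)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        base=st.integers(2, 6),
        added=st.integers(0, 3),
        modified_count=st.integers(0, 2),
    )
    def test_incrementality_law_k_plus_m(self, base, added, modified_count):
        """Adding k files and modifying m yields exactly k+m changed datums."""
        modified_count = min(modified_count, base)
        old_files = {f"/f{i}.csv": f"v{i}".encode() for i in range(base)}
        new_files = dict(old_files)
        for i in range(added):
            new_files[f"/new{i}.csv"] = f"n{i}".encode()
        for i in range(modified_count):
            new_files[f"/f{i}.csv"] = f"v{i}-edited".encode()
        diff = datum_diff(make_tree(old_files), make_tree(new_files), "/*")
        assert len(diff.changed) == added + modified_count
        assert len(diff.unchanged) == base - modified_count
        assert diff.removed == ()
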