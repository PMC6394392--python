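import pytest

from datumflow import (
    AlreadyExistsError,
    NotFoundError,
    ValidationError,
    Workspace,
)


class TestRepoLifecycle:
    def test_create_repo_starts_empty(self, ws):
        ws.create_repo("RepoA")
        assert ws.list_commits("RepoA") == []
        assert ws.head_commit("RepoA") is None

    def test_duplicate_name_rejected(self, ws):
        ws.create_repo("RepoA")
        with pytest.raises(AlreadyExistsError):
            ws.create_repo("RepoA")

    @pytest.mark.parametrize("name", ["bad/name", "", "with space", "dot.dot"])
    def test_invalid_names_rejected(self, ws, name):
        with pytest.raises(ValidationError):
            ws.create_repo(name)

    def test_unknown_repo_raises(self, ws):
        with pytest.raises(NotFoundError):
            ws.list_commits("nope")


class TestCommits:
    def test_first_commit_gets_ordinal_one(self, ws):
        ws.create_repo("RepoA")
        commit = ws.commit_files("RepoA", {"/a.csv": b"1"})
        assert commit.id == "RepoA@1"
        assert len(commit.tree) == 1
        assert ws.get_file("RepoA@1", "/a.csv") == b"1"

    def test_empty_change_set_preserves_tree_hash(self, ws):
        ws.create_repo("RepoA")
        first = ws.commit_files("RepoA", {"/a.csv": b"1"})
        second = ws.commit_files("RepoA", {})
        assert second.id == "RepoA@2"
        assert second.tree_hash() == first.tree_hash()
        assert second.parent == first.id

    def test_history_preserved_after_deletion(self, ws):
        ws.create_repo("RepoA")
        ws.commit_files("RepoA", {"/x": b"original"})
        ws.commit_files("RepoA", {"/x": None})
        assert ws.get_file("RepoA@1", "/x") == b"original"
        with pytest.raises(NotFoundError):
            ws.get_file("RepoA@2", "/x")

    def test_get_missing_path_raises(self, ws):
        ws.create_repo("RepoA")
        ws.commit_files("RepoA", {"/a": b"1"})
        with pytest.raises(NotFoundError):
            ws.get_file("RepoA@1", "/missing")

    def test_commit_chain_terminates_at_parentless_root(self, ws):
        ws.create_repo("RepoA")
        for i in range(5):
            ws.commit_files("RepoA", {f"/f{i}": str(i).encode()})
        seen = set()
        commit = ws.head_commit("RepoA")
        while commit.parent is not None:
            assert commit.id not in seen  # no cycles
            seen.add(commit.id)
            commit = ws.get_commit(commit.parent)
        assert commit.id == "RepoA@1"


class TestCopyOnWrite:
    def test_new_file_on_large_parent_stores_one_blob(self, ws):
        ws.create_repo("RepoA")
        ws.commit_files("RepoA", {f"/s{i:03d}.csv": f"sample-{i}".encode() for i in range(137)})
        before = ws.store_stats().object_count
        commit = ws.commit_files("RepoA", {"/s137.csv": b"sample-137"})
        assert ws.store_stats().object_count == before + 1
        assert len(commit.tree) == 138

    def test_unchanged_paths_share_addresses_with_parent(self, ws):
        ws.create_repo("RepoA")
        first = ws.commit_files("RepoA", {"/keep": b"same", "/edit": b"v1"})
        second = ws.commit_files("RepoA", {"/edit": b"v2"})
        assert second.tree.get("/keep") == first.tree.get("/keep")
        assert second.tree.get("/edit") != first.tree.get("/edit")


class TestDiffCommits:
    def test_diff_identity(self, ws):
        ws.create_repo("RepoA")
        commit = ws.commit_files("RepoA", {"/a": b"1"})
        assert ws.diff_commits(commit.id, commit.id).is_empty

    def test_diff_classification(self, ws):
        ws.create_repo("RepoA")
        ws.commit_files("RepoA", {"/a": b"X", "/b": b"Y"})
        ws.commit_files("RepoA", {"/b": b"Z", "/c": b"W"})
        result = ws.diff_commits("RepoA@1", "RepoA@2")
        assert result.added == {"/c"}
        assert result.modified == {"/b"}
        assert result.deleted == frozenset()

    def test_cross_repo_diff_rejected(self, ws):
        ws.create_repo("RepoA")
        ws.create_repo("RepoB")
        ws.commit_files("RepoA", {"/a": b"1"})
        ws.commit_files("RepoB", {"/a": b"1"})
        with pytest.raises(ValidationError):
            ws.diff_commits("RepoA@1", "RepoB@1")


class TestPersistence:
    def test_catalog_survives_reopen(self, tmp_path):
        root = tmp_path / "ws"
        first = Workspace(root)
        first.create_repo("RepoA")
        commit = first.commit_files("RepoA", {"/a.csv": b"persisted"})
        tree_hash = commit.tree_hash()
        first.close()

        reopened = Workspace(root)
        assert reopened.list_repos() == ["RepoA"]
        assert reopened.head_commit("RepoA").tree_hash() == tree_hash
        assert reopened.get_file("RepoA@1", "/a.csv") == b"persisted"
        reopened.close()
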