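"""Bundles, invocation, installation and the all-or-nothing run orchestration."""

import hashlib
import json
import os
from pathlib import Path

import pytest

import refstash as rs
from refstash.engine import ENTRIES_FILENAME, PARAMS_FILENAME


def _registry_snapshot(env):
    """(loc bytes per table, sorted data_root file list) for state comparison."""
    locs = {
        t: (env.registry.loc_file(t).read_bytes()
            if env.registry.loc_file(t).exists() else b"")
        for t in env.registry.table_names
    }
    files = sorted(
        str(p.relative_to(env.paths["data_root"]))
        for p in env.paths["data_root"].rglob("*")
    )
    return locs, files


# ---------------------------------------------------------------------------
# param bundle
# ---------------------------------------------------------------------------

def test_param_bundle_round_trips_and_lands_in_staging(env, genome):
    recipe = env.recipe_store.get("toy_index")
    norm = rs.validate_bindings(recipe, {"dbkey": "hg19", "fasta": str(genome)})
    staging = env.paths["scratch_root"] / "run1"
    bundle = rs.build_param_bundle(
        recipe, norm, staging, {"data_root": str(env.paths["data_root"])}
    )
    text = (staging / PARAMS_FILENAME).read_text()
    parsed = rs.ParamBundle.from_json(text)
    assert parsed.params["dbkey"] == "hg19"
    assert parsed.staging_dir == str(staging)
    assert parsed.settings["data_root"] == str(env.paths["data_root"])
    assert parsed == bundle
    # stable serialization
    assert text == bundle.to_json()


def test_param_bundle_requires_fresh_staging(env, genome):
    recipe = env.recipe_store.get("toy_index")
    norm = rs.validate_bindings(recipe, {"dbkey": "x", "fasta": str(genome)})
    staging = env.paths["scratch_root"] / "dirty"
    staging.mkdir()
    (staging / "leftover").write_text("x")
    with pytest.raises(rs.BundleError, match="not empty"):
        rs.build_param_bundle(recipe, norm, staging, {"data_root": "/d"})


def test_distinct_runs_use_distinct_staging_dirs(env, genome):
    r1 = env.run("toy_multi", dbkey="a")
    r2 = env.run("toy_multi", dbkey="b")
    assert r1.run_id != r2.run_id
    assert (env.paths["scratch_root"] / r1.run_id) != \
        (env.paths["scratch_root"] / r2.run_id)


# ---------------------------------------------------------------------------
# invoke
# ---------------------------------------------------------------------------

def test_builtin_invoke_writes_entries_json(env, genome):
    recipe = env.recipe_store.get("toy_index")
    norm = rs.validate_bindings(recipe, {"dbkey": "hg19", "fasta": str(genome)})
    staging = env.paths["scratch_root"] / "inv"
    bundle = rs.build_param_bundle(
        recipe, norm, staging, {"data_root": str(env.paths["data_root"])}
    )
    status, log = rs.invoke(recipe, bundle)
    assert status == 0
    assert (staging / ENTRIES_FILENAME).is_file()
    assert "2 sequences" in log


def test_missing_executable_fails_without_committing(env, genome):
    doc = rs.fixture_recipe_docs()["toy_index_cmd"]
    doc["id"] = "broken_cmd"
    doc["command"] = ["/no/such/binary_xyz"]
    env.recipe_store.add(rs.parse_recipe(doc, env.table_specs))
    before = _registry_snapshot(env)
    with pytest.raises(rs.RunFailure) as exc:
        env.run("broken_cmd", dbkey="x", fasta=str(genome))
    assert exc.value.record.status == "failed"
    assert _registry_snapshot(env) == before


def test_nonzero_exit_captures_stderr_in_log(env, tmp_path):
    bad = tmp_path / "empty.fa"
    bad.write_text("")  # exists but empty -> toy_index rejects it
    with pytest.raises(rs.RunFailure) as exc:
        env.run("toy_index", dbkey="x", fasta=str(bad))
    rec = exc.value.record
    assert rec.status == "failed"
    assert "not FASTA" in rec.log


def test_subprocess_and_builtin_paths_honor_one_contract(env, genome):
    """The command twin of toy_index produces identical registry rows and files."""
    rec_b = env.run("toy_index", dbkey="hg19", fasta=str(genome))
    fresh = env.fresh_registry("cmdtwin")
    rec_c = rs.run_recipe(
        fresh, env.recipe_store, "toy_index_cmd",
        {"dbkey": "hg19", "fasta": str(genome)},
        scratch_root=env.paths["scratch_root"],
    )
    builtin_entry = env.registry.query_entries("toy_indexes")[0]
    cmd_entry = fresh.query_entries("toy_indexes")[0]
    # identical modulo the differing data roots
    fix = lambda e, root: {k: v.replace(str(root), "DR") for k, v in e.values.items()}
    assert fix(builtin_entry, env.paths["data_root"]) == \
        fix(cmd_entry, fresh.data_root)
    assert {m.relpath: m.sha256 for m in rec_b.manifest} == \
        {m.relpath: m.sha256 for m in rec_c.manifest}


# ---------------------------------------------------------------------------
# parse_entry_bundle
# ---------------------------------------------------------------------------

def test_entry_bundle_parses_declared_table(env):
    recipe = env.recipe_store.get("toy_index")
    text = json.dumps({"data_tables": {"toy_indexes": [
        {"value": "hg19", "dbkey": "hg19", "name": "Human hg19", "path": "hg19.fa"}
    ]}})
    bundle = rs.parse_entry_bundle(text, recipe)
    assert bundle.total_entries() == 1
    assert bundle.data_tables["toy_indexes"][0]["value"] == "hg19"


def test_entry_bundle_empty_is_legal(env):
    recipe = env.recipe_store.get("toy_index")
    assert rs.parse_entry_bundle('{"data_tables": {}}', recipe).total_entries() == 0


@pytest.mark.parametrize("text,match", [
    ('{"data_tables": {"all_fasta": []}}', "not declared"),   # undeclared table
    ('{"data_tables": {"toy_indexes": [{"value": 3}]}}', "non-string"),
    ('{"nope": 1}', "data_tables"),
    ('not json', "not valid JSON"),
])
def test_entry_bundle_rejects_contract_violations(env, text, match):
    recipe = env.recipe_store.get("toy_index")
    with pytest.raises(rs.BundleError, match=match):
        rs.parse_entry_bundle(text, recipe)


# ---------------------------------------------------------------------------
# install_files
# ---------------------------------------------------------------------------

def _digest_walk(root: Path) -> dict:
    """Independent manifest oracle: plain directory walk + hashlib."""
    out = {}
    for dirpath, _, names in os.walk(root):
        for name in names:
            p = Path(dirpath) / name
            out[str(p.relative_to(root))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def test_copy_dir_manifest_matches_independent_digests(tmp_path):
    staging = tmp_path / "staging"
    staging.mkdir()
    (staging / PARAMS_FILENAME).write_text("{}")
    (staging / ENTRIES_FILENAME).write_text("{}")
    (staging / "hg19.fa").write_text(">s\nACGT\n")
    (staging / "hg19.fa.idx").write_bytes(b"\x00\x01binary-ish")
    asset = tmp_path / "data" / "toy_indexes" / "hg19"
    manifest = rs.install_files(staging, asset, "copy_dir")
    assert sorted(m.relpath for m in manifest) == ["hg19.fa", "hg19.fa.idx"]
    assert {m.relpath: m.sha256 for m in manifest} == _digest_walk(asset)
    # bundle documents never install
    assert not (asset / PARAMS_FILENAME).exists()


def test_policy_none_installs_nothing(tmp_path):
    staging = tmp_path / "staging"
    staging.mkdir()
    (staging / "f").write_text("x")
    asset = tmp_path / "asset"
    assert rs.install_files(staging, asset, "none") == []
    assert not asset.exists()


def test_copy_file_installs_only_named_files(tmp_path):
    staging = tmp_path / "staging"
    staging.mkdir()
    (staging / "keep.fa").write_text("a")
    (staging / "skip.fa").write_text("b")
    asset = tmp_path / "asset"
    manifest = rs.install_files(staging, asset, "copy_file", files=["keep.fa"])
    assert [m.relpath for m in manifest] == ["keep.fa"]
    assert not (asset / "skip.fa").exists()


def test_populated_asset_dir_is_a_collision(tmp_path):
    staging = tmp_path / "staging"
    staging.mkdir()
    (staging / "f").write_text("x")
    asset = tmp_path / "asset"
    asset.mkdir()
    (asset / "old").write_text("y")
    with pytest.raises(rs.InstallCollisionError):
        rs.install_files(staging, asset, "copy_dir")
    assert (asset / "old").read_text() == "y"  # untouched


def test_manifest_item_rejects_escaping_paths():
    with pytest.raises(rs.BundleError, match="escapes"):
        rs.FileManifestItem(relpath="../evil", size=1, sha256="0" * 64)
    with pytest.raises(rs.BundleError, match="hex"):
        rs.FileManifestItem(relpath="ok", size=1, sha256="XYZ")


# ---------------------------------------------------------------------------
# run_recipe orchestration
# ---------------------------------------------------------------------------

def test_end_to_end_two_stage_run(env, genome):
    r1 = env.run("fetch_local_fasta", dbkey="hg19", name="Human hg19",
                 fasta=str(genome))
    r2 = env.run("toy_index", dbkey="hg19", fasta=str(genome))
    assert r1.status == r2.status == "succeeded"
    assert r1.added_counts == {"all_fasta": 1}
    assert r2.added_counts == {"toy_indexes": 1}
    # queryable immediately, and the loc file holds exactly the rendered line
    [fa_entry] = env.registry.query_entries("all_fasta")
    [idx_entry] = env.registry.query_entries("toy_indexes")
    assert fa_entry["path"].startswith(str(env.paths["data_root"]))
    assert Path(idx_entry["path"]).is_file()
    spec = env.table_specs["toy_indexes"]
    assert env.registry.loc_file("toy_indexes").read_text() == \
        rs.render_loc_text([idx_entry], spec)
    # installed artefacts: fasta copy + .sizes + .sum
    assert sorted(m.relpath.split("/")[-1] for m in r2.manifest) == \
        ["genome.fa", "genome.fa.sizes", "genome.fa.sum"]


def test_rerun_is_idempotent(env, genome):
    """Identical bindings a second time: success, 0 added, loc byte-identical."""
    env.run("toy_index", dbkey="hg19", fasta=str(genome))
    loc_before = env.registry.loc_file("toy_indexes").read_bytes()
    files_before = sorted(env.paths["data_root"].rglob("*"))
    rec = env.run("toy_index", dbkey="hg19", fasta=str(genome))
    assert rec.status == "succeeded"
    assert rec.entries_added() == 0
    assert env.registry.loc_file("toy_indexes").read_bytes() == loc_before
    assert sorted(env.paths["data_root"].rglob("*")) == files_before


def test_conflicting_rerun_fails_before_installing(env, genome, tmp_path):
    """Same key but different content must error without touching anything."""
    env.run("toy_index", dbkey="hg19", fasta=str(genome))
    other = rs.make_fasta(rs.SyntheticGenomeSpec(seed=8), tmp_path / "other.fa")
    before = _registry_snapshot(env)
    with pytest.raises(rs.RunFailure) as exc:
        env.run("toy_index", dbkey="hg19", fasta=str(other))
    assert "already present" in str(exc.value)
    assert _registry_snapshot(env) == before


def test_rerun_without_files_is_duplicate_skipped(env):
    env.run("toy_multi", dbkey="dm3")
    locs_before = {
        t: env.registry.loc_file(t).read_bytes()
        for t in ("toy_kmers", "toy_stats")
    }
    rec = env.run("toy_multi", dbkey="dm3")
    assert rec.status == "succeeded"
    assert rec.entries_added() == 0  # full-row duplicates, silently skipped
    for t, before in locs_before.items():
        assert env.registry.loc_file(t).read_bytes() == before


def test_multi_table_conservation(env):
    rec = env.run("toy_multi", dbkey="dm3")
    assert rec.added_counts == {"toy_kmers": 2, "toy_stats": 3}
    assert len(env.registry.query_entries("toy_kmers")) == 2
    assert len(env.registry.query_entries("toy_stats")) == 3


INJECTION_POINTS = ["before_invoke", "after_invoke", "after_parse",
                    "after_install", "mid_append"]


@pytest.mark.parametrize("point", INJECTION_POINTS)
def test_failure_injection_leaves_no_trace(env, genome, point):
    """A crash at any stage leaves loc files and data_root exactly as before."""
    env.run("fetch_local_fasta", dbkey="mm10", name="Mouse", fasta=str(genome))
    before = _registry_snapshot(env)

    def failpoint(stage):
        if stage == point:
            raise rs.InjectedFailure(stage)

    with pytest.raises(rs.RunFailure) as exc:
        env.run("toy_index", failpoint=failpoint, dbkey="hg19",
                fasta=str(genome))
    record = exc.value.record
    assert record.status in ("failed", "rolled_back")
    assert _registry_snapshot(env) == before
    # the record itself is persisted
    assert env.provenance.load_record(record.run_id).status == record.status


def test_mid_append_failure_rolls_back_committed_table(env):
    """Failure between two table appends must rewind the already-written one."""
    before = _registry_snapshot(env)

    def failpoint(stage):
        if stage == "mid_append":
            raise rs.InjectedFailure(stage)

    with pytest.raises(rs.RunFailure) as exc:
        env.run("toy_multi", failpoint=failpoint, dbkey="dm3")
    assert exc.value.record.status == "rolled_back"
    assert _registry_snapshot(env) == before
    assert env.registry.query_entries("toy_kmers") == []
    assert env.registry.query_entries("toy_stats") == []


def test_manifest_paths_stay_inside_data_root(env, genome):
    rec = env.run("toy_index", dbkey="hg19", fasta=str(genome))
    for item in rec.manifest:
        assert ".." not in Path(item.relpath).parts
        assert (env.paths["data_root"] / item.relpath).is_file()
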