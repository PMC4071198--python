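import dataclasses
from pathlib import Path

import pytest
import yaml

import refstash as rs


@dataclasses.dataclass
class Env:
    """One fully wired fixture workspace: registry, recipes, provenance."""

    paths: dict
    registry: rs.Registry
    table_specs: dict
    recipe_store: rs.RecipeStore
    provenance: rs.ProvenanceStore

    def run(self, recipe_id: str, failpoint=None, **bindings) -> rs.RunRecord:
        return rs.run_recipe(
            self.registry, self.recipe_store, recipe_id,
            {k: str(v) for k, v in bindings.items()},
            scratch_root=self.paths["scratch_root"],
            provenance_store=self.provenance,
            failpoint=failpoint,
        )

    def fresh_registry(self, tag: str) -> rs.Registry:
        doc = yaml.safe_load(self.paths["registry_config"].read_text())
        root = self.paths["root"] / tag
        return rs.load_registry(doc, root / "registry", root / "data")


def build_env(root: Path) -> Env:
    paths = rs.write_fixture_workspace(root)
    doc = yaml.safe_load(paths["registry_config"].read_text())
    table_specs = {s.name: s for s in rs.parse_registry_config(doc)}
    registry = rs.load_registry(doc, paths["registry_root"], paths["data_root"])
    store = rs.RecipeStore()
    for f in sorted(paths["recipes_dir"].iterdir()):
        store.add(rs.parse_recipe(yaml.safe_load(f.read_text()), table_specs))
    return Env(
        paths=paths, registry=registry, table_specs=table_specs,
        recipe_store=store, provenance=rs.ProvenanceStore(paths["provenance_root"]),
    )


@pytest.fixture
def env(tmp_path) -> Env:
    return build_env(tmp_path / "ws")


@pytest.fixture
def genome(env) -> Path:
    """A small deterministic FASTA (2 sequences x 120 bases, seed 7)."""
    return rs.make_fasta(
        rs.SyntheticGenomeSpec(seed=7, n_sequences=2, length=120),
        env.paths["root"] / "genome.fa",
    )


@pytest.fixture
def four_col_spec() -> rs.DataTableSpec:
    return rs.DataTableSpec(
        name="bwa_indexes",
        columns=tuple(
            rs.ColumnSpec(n, i) for i, n in enumerate(("value", "dbkey", "name", "path"))
        ),
        loc_path="bwa_indexes.loc",
    )


@pytest.fixture
def hg19_entry() -> rs.TableEntry:
    return rs.TableEntry(
        {"value": "hg19", "dbkey": "hg19", "name": "Human hg19",
         "path": "/data/hg19.fa"}
    )
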