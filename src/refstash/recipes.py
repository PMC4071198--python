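"""Declarative build recipes and value finalization.

A *recipe* describes one reference-data builder: the parameters an
administrator supplies (genome build key, source FASTA, indexing algorithm,
...), the command to run — either a subprocess token list or the name of a
builtin in-process action — and, per output data table, how the raw entry
values the tool emits are *finalized* before registration.

Finalization is the key contract: a builder emits base values (typically a
bare file name such as ``genome_build.fa``) and never touches the registry
itself; declared *value translations* rewrite selected columns into their
final stored form (typically the absolute installed path under the managed
data root), while every untranslated column — the ID, dbkey and display
text — passes through verbatim.

Two translation kinds are provided:

``template``
    substitute ``${data_root}``, ``${table}``, ``${value}``, ``${dbkey}`` and
    ``${raw}`` into a template string; the default installed-asset layout is
    ``${data_root}/${table}/${value}/${raw}``.
``abspath``
    join a relative raw value under the data root; absolute values pass
    through unchanged (hence idempotent).

Commands are token lists, not shell strings: parameter substitution happens
per token, so a parameter value can never smuggle in extra arguments or shell
syntax. Unknown ``${...}`` placeholders are parse-time errors, never silent
empty strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import BindingError, RecipeError, TranslationError
from .registry import DataTableSpec, TableEntry

PARAM_KINDS = ("text", "integer", "boolean", "choice", "input_path")
TRANSLATION_KINDS = ("template", "abspath")
MOVE_POLICIES = ("copy_dir", "copy_file", "none")

#: placeholders a template translation may reference
TEMPLATE_PLACEHOLDERS = ("data_root", "table", "value", "dbkey", "raw")

#: the decided installed-asset layout: per-build directories under data_root
DEFAULT_PATH_TEMPLATE = "${data_root}/${table}/${value}/${raw}"

_PLACEHOLDER_RE = re.compile(r"\$\{([^}]*)\}")
_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.-]*$")

_TRUE = {"true", "yes", "1", "on"}
_FALSE = {"false", "no", "0", "off"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamDecl:
    name: str
    kind: str = "text"
    default: str | None = None
    choices: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in PARAM_KINDS:
            raise RecipeError(f"param {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "choice" and not self.choices:
            raise RecipeError(f"param {self.name!r}: choice kind needs choices")
        if self.kind != "choice" and self.choices:
            raise RecipeError(f"param {self.name!r}: choices only valid for kind=choice")
        if self.default is not None:
            try:
                _coerce(self, self.default, check_paths=False)
            except BindingError as exc:
                raise RecipeError(f"param {self.name!r}: invalid default: {exc}") from None


@dataclass(frozen=True)
class ValueTranslation:
    column: str
    kind: str
    template: str | None = None

    def __post_init__(self):
        if self.kind not in TRANSLATION_KINDS:
            raise RecipeError(
                f"translation on {self.column!r}: unknown kind {self.kind!r}"
            )
        if self.kind == "template":
            if self.template is None:
                raise RecipeError(
                    f"translation on {self.column!r}: template kind needs a template"
                )
            for ph in _PLACEHOLDER_RE.findall(self.template):
                if ph not in TEMPLATE_PLACEHOLDERS:
                    raise RecipeError(
                        f"translation on {self.column!r}: unknown placeholder "
                        f"${{{ph}}} (allowed: {', '.join(TEMPLATE_PLACEHOLDERS)})"
                    )
        elif self.template is not None:
            raise RecipeError(
                f"translation on {self.column!r}: template only valid for kind=template"
            )


@dataclass(frozen=True)
class OutputDecl:
    table: str
    translations: tuple[ValueTranslation, ...] = ()
    move_policy: str = "copy_dir"

    def __post_init__(self):
        if self.move_policy not in MOVE_POLICIES:
            raise RecipeError(
                f"output {self.table!r}: unknown move_policy {self.move_policy!r}"
            )
        cols = [t.column for t in self.translations]
        if len(set(cols)) != len(cols):
            raise RecipeError(
                f"output {self.table!r}: multiple translations for one column"
            )

    def translation_for(self, column: str) -> ValueTranslation | None:
        for t in self.translations:
            if t.column == column:
                return t
        return None


@dataclass(frozen=True)
class RecipeSpec:
    """One validated recipe: identity, parameters, command, outputs."""

    id: str
    version: str
    name: str
    description: str
    params: tuple[ParamDecl, ...]
    outputs: tuple[OutputDecl, ...]
    command: tuple[str, ...] | None = None  # subprocess token list
    builtin: str | None = None              # or in-process action name

    def __post_init__(self):
        if (self.command is None) == (self.builtin is None):
            raise RecipeError(
                f"recipe {self.id!r}: exactly one of command/builtin required"
            )
        if not self.outputs:
            raise RecipeError(f"recipe {self.id!r}: at least one output required")

    def param(self, name: str) -> ParamDecl:
        for p in self.params:
            if p.name == name:
                return p
        raise RecipeError(f"recipe {self.id!r}: no param {name!r}")


class RecipeStore:
    """In-memory collection of recipes keyed by (id, version)."""

    def __init__(self):
        self._recipes: dict[tuple[str, str], RecipeSpec] = {}
        self._order: list[tuple[str, str]] = []

    def add(self, recipe: RecipeSpec) -> None:
        key = (recipe.id, recipe.version)
        if key in self._recipes:
            raise RecipeError(f"recipe {recipe.id!r} version {recipe.version!r} already registered")
        self._recipes[key] = recipe
        self._order.append(key)

    def get(self, recipe_id: str, version: str | None = None) -> RecipeSpec:
        if version is not None:
            try:
                return self._recipes[(recipe_id, version)]
            except KeyError:
                raise RecipeError(
                    f"recipe {recipe_id!r} version {version!r} not in store"
                ) from None
        candidates = [self._recipes[k] for k in self._order if k[0] == recipe_id]
        if not candidates:
            raise RecipeError(f"recipe {recipe_id!r} not in store")
        return candidates[-1]  # latest registered

    def __contains__(self, recipe_id: str) -> bool:
        return any(k[0] == recipe_id for k in self._recipes)

    def ids(self) -> list[str]:
        seen, out = set(), []
        for rid, _ in self._order:
            if rid not in seen:
                seen.add(rid)
                out.append(rid)
        return out


# ---------------------------------------------------------------------------
# recipe parsing
# ---------------------------------------------------------------------------

def parse_recipe(doc, registry_config: Mapping[str, DataTableSpec]) -> RecipeSpec:
    """Validate a parsed recipe document against the registry's table specs.

    *registry_config* maps table name -> :class:`DataTableSpec`; every output
    table and every translated column must exist there, and every ``${param}``
    placeholder in the command must name a declared parameter.
    """
    if not isinstance(doc, Mapping):
        raise RecipeError("recipe document must be a mapping")
    for req in ("id", "version"):
        if not doc.get(req):
            raise RecipeError(f"recipe document missing required field {req!r}")
    rid = str(doc["id"])
    if not _IDENT_RE.match(rid):
        raise RecipeError(f"invalid recipe id {rid!r}")

    params = tuple(
        ParamDecl(
            name=str(p["name"]),
            kind=str(p.get("kind", "text")),
            default=None if p.get("default") is None else str(p["default"]),
            choices=tuple(str(c) for c in p.get("choices", ())),
        )
        for p in doc.get("params", ())
    )
    names = [p.name for p in params]
    if len(set(names)) != len(names):
        raise RecipeError(f"recipe {rid!r}: duplicate param names")

    outputs = []
    for o in doc.get("outputs", ()):
        table = str(o["table"])
        if table not in registry_config:
            raise RecipeError(
                f"recipe {rid!r}: output table {table!r} not declared in registry config"
            )
        tspec = registry_config[table]
        translations = tuple(
            ValueTranslation(
                column=str(t["column"]),
                kind=str(t["kind"]),
                template=t.get("template"),
            )
            for t in o.get("translations", ())
        )
        for t in translations:
            if t.column not in tspec.column_names:
                raise RecipeError(
                    f"recipe {rid!r}: translation on unknown column {t.column!r} "
                    f"of table {table!r}"
                )
        outputs.append(
            OutputDecl(table=table, translations=translations,
                       move_policy=str(o.get("move_policy", "copy_dir")))
        )

    command = doc.get("command")
    builtin = doc.get("builtin")
    if command is not None:
        if isinstance(command, (str, bytes)) or not isinstance(command, Sequence):
            raise RecipeError(f"recipe {rid!r}: command must be a token list")
        command = tuple(str(tok) for tok in command)
        declared = set(names)
        for tok in command:
            for ph in _PLACEHOLDER_RE.findall(tok):
                if ph not in declared:
                    raise RecipeError(
                        f"recipe {rid!r}: command placeholder ${{{ph}}} names no "
                        f"declared param"
                    )

    return RecipeSpec(
        id=rid,
        version=str(doc["version"]),
        name=str(doc.get("name", rid)),
        description=str(doc.get("description", "")),
        params=params,
        outputs=tuple(outputs),
        command=command,
        builtin=None if builtin is None else str(builtin),
    )


# ---------------------------------------------------------------------------
# bindings
# ---------------------------------------------------------------------------

def _coerce(decl: ParamDecl, value: str, *, check_paths: bool = True):
    if decl.kind == "text":
        return str(value)
    if decl.kind == "integer":
        try:
            return int(str(value), 10)
        except ValueError:
            raise BindingError(f"param {decl.name!r}: {value!r} is not an integer") from None
    if decl.kind == "boolean":
        low = str(value).strip().lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise BindingError(f"param {decl.name!r}: {value!r} is not a boolean")
    if decl.kind == "choice":
        sval = str(value)
        if sval not in decl.choices:
            raise BindingError(
                f"param {decl.name!r}: {sval!r} not among choices {list(decl.choices)}"
            )
        return sval
    if decl.kind == "input_path":
        path = Path(str(value)).expanduser()
        if check_paths:
            path = path.resolve()
            if not path.is_file():
                raise BindingError(f"param {decl.name!r}: no such file {value!r}")
        return str(path)
    raise AssertionError(decl.kind)


def validate_bindings(recipe: RecipeSpec, bindings: Mapping[str, str]) -> dict:
    """Fill defaults, coerce types, and resolve input paths to absolute paths.

    Returns a new mapping param -> normalized value (str/int/bool). Unknown
    binding names, missing required params, bad choices and nonexistent input
    paths are :class:`BindingError`\\ s.
    """
    declared = {p.name for p in recipe.params}
    unknown = set(bindings) - declared
    if unknown:
        raise BindingError(
            f"recipe {recipe.id!r}: unknown param(s) {sorted(unknown)}"
        )
    normalized: dict = {}
    for decl in recipe.params:
        if decl.name in bindings:
            normalized[decl.name] = _coerce(decl, bindings[decl.name])
        elif decl.default is not None:
            normalized[decl.name] = _coerce(decl, decl.default)
        else:
            raise BindingError(
                f"recipe {recipe.id!r}: missing required param {decl.name!r}"
            )
    return normalized


# ---------------------------------------------------------------------------
# value translation / entry finalization
# ---------------------------------------------------------------------------

def apply_translation(tr: ValueTranslation, raw: str, ctx: Mapping[str, str]) -> str:
    """Apply one translation to a raw value.

    *ctx* must supply ``data_root``, ``table``, ``value`` and ``dbkey``;
    ``raw`` is bound to the incoming value. ``abspath`` joins a relative raw
    under ``data_root`` and leaves absolute values alone.
    """
    for key in ("data_root", "table", "value"):
        if key not in ctx:
            raise TranslationError(f"translation context missing {key!r}")
    if tr.kind == "abspath":
        if raw.startswith("/"):
            return raw
        return str(Path(ctx["data_root"]) / raw)
    # kind == "template"
    mapping = {
        "data_root": str(ctx["data_root"]),
        "table": str(ctx["table"]),
        "value": str(ctx["value"]),
        "dbkey": str(ctx.get("dbkey", "")),
        "raw": raw,
    }

    def _sub(match: re.Match) -> str:
        name = match.group(1)
        if name not in mapping:  # defensive: parse already rejects these
            raise TranslationError(f"unknown placeholder ${{{name}}}")
        return mapping[name]

    return _PLACEHOLDER_RE.sub(_sub, tr.template or "")


def finalize_entry(raw_entry: Mapping[str, str], out: OutputDecl,
                   ctx: Mapping[str, str], table_spec: DataTableSpec) -> TableEntry:
    """Finalize one raw entry for registration.

    Translated columns are rewritten by :func:`apply_translation`; every other
    column passes through verbatim. The result must satisfy the target
    table's entry contract (all columns present, key non-empty, no TABs).
    """
    if table_spec.key_column not in raw_entry:
        raise TranslationError(
            f"raw entry for table {out.table!r} missing key column "
            f"{table_spec.key_column!r}"
        )
    ctx = dict(ctx)
    ctx.setdefault("table", out.table)
    ctx["value"] = str(raw_entry[table_spec.key_column])
    if "dbkey" in raw_entry:
        ctx.setdefault("dbkey", str(raw_entry["dbkey"]))
    values: dict[str, str] = {}
    for col, raw_val in raw_entry.items():
        tr = out.translation_for(col)
        values[col] = apply_translation(tr, str(raw_val), ctx) if tr else str(raw_val)
    entry = TableEntry(values)
    entry.validate(table_spec)
    return entry
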