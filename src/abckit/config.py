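"""Plain-text ``key value`` configuration files.

The dialect is deliberately small and line oriented:

* comment lines start with ``//`` or ``#`` (leading whitespace allowed);
* every other non-blank line is split on the first whitespace run into a
  key and a value (the value may itself contain whitespace);
* a handful of *repeatable* directives (``PRIOR``, ``RULE``, ``SIMULATOR``,
  ``POSTHOOK``) may occur many times and accumulate in order; any other key
  occurring twice is a parse error;
* command-line ``KEY=VALUE`` overrides replace file values.

Values are stored as strings and coerced (float/int/bool) at lookup time so
that a missing or malformed value produces an error naming the key rather
than a silent default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ConfigError

#: Directives that may legitimately occur more than once in one file.
REPEATABLE_KEYS = frozenset({"PRIOR", "RULE", "SIMULATOR", "POSTHOOK"})

_MISSING = object()


@dataclass
class Config:
    """Parsed configuration: single-valued entries plus repeatable directives."""

    entries: dict[str, str] = field(default_factory=dict)
    repeated: dict[str, list[str]] = field(default_factory=dict)
    source_path: str = "<string>"

    def __contains__(self, key: str) -> bool:
        return key in self.entries or key in self.repeated

    def get(self, key: str, default=_MISSING) -> str:
        """Look up a single-valued key; missing key with no default is an error."""
        if key in self.entries:
            return self.entries[key]
        if default is _MISSING:
            raise ConfigError(f"{self.source_path}: required key {key!r} is missing")
        return default

    def get_float(self, key: str, default=_MISSING) -> float:
        raw = self.get(key, default)
        try:
            return float(raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{self.source_path}: key {key!r}: not a number: {raw!r}") from exc

    def get_int(self, key: str, default=_MISSING) -> int:
        raw = self.get(key, default)
        try:
            return int(raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{self.source_path}: key {key!r}: not an integer: {raw!r}") from exc

    def get_list(self, key: str) -> list[str]:
        """All occurrences of a repeatable directive, in file order."""
        return list(self.repeated.get(key, []))

    def with_overrides(self, overrides: dict[str, str]) -> "Config":
        """Return a copy with ``overrides`` replacing single-valued entries."""
        for key in overrides:
            if key in REPEATABLE_KEYS:
                raise ConfigError(f"repeatable key {key!r} cannot be overridden on the command line")
        merged = dict(self.entries)
        merged.update(overrides)
        return Config(entries=merged,
                      repeated={k: list(v) for k, v in self.repeated.items()},
                      source_path=self.source_path)

    def resolved_text(self) -> str:
        """Render the effective configuration, one ``key value`` per line."""
        lines = [f"{k} {v}" for k, v in self.entries.items()]
        for key, values in self.repeated.items():
            lines.extend(f"{key} {v}" for v in values)
        return "\n".join(lines)


def parse_config(text: str, source_path: str = "<string>") -> Config:
    """Parse configuration text into a :class:`Config`.

    Raises
    ------
    ConfigError
        On a duplicate (non-repeatable) key or a line with no value, naming
        the offending line number.
    """
    entries: dict[str, str] = {}
    repeated: dict[str, list[str]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("//") or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) == 1:
            raise ConfigError(f"{source_path}:{lineno}: key {parts[0]!r} has no value")
        key, value = parts[0], parts[1].strip()
        if key in REPEATABLE_KEYS:
            repeated.setdefault(key, []).append(value)
        elif key in entries:
            raise ConfigError(f"{source_path}:{lineno}: duplicate key {key!r}")
        else:
            entries[key] = value
    return Config(entries=entries, repeated=repeated, source_path=source_path)


def read_config(path) -> Config:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_config(fh.read(), source_path=str(path))


def parse_overrides(tokens) -> dict[str, str]:
    """Parse command-line ``KEY=VALUE`` tokens into an override mapping."""
    overrides: dict[str, str] = {}
    for token in tokens:
        if "=" not in token:
            raise ConfigError(f"override {token!r} is not of the form KEY=VALUE")
        key, value = token.split("=", 1)
        overrides[key] = value
    return overrides
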