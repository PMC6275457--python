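"""Exception hierarchy shared across the pipeline."""


class LgtScreenError(Exception):
    """Base class for all package errors."""


class ParseError(LgtScreenError):
    """A line of an input file could not be parsed."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class DialectError(ParseError):
    """Wrong column count for the declared file dialect."""


class SchemaError(LgtScreenError):
    """A required column is missing from a headered table."""


class ValidationError(LgtScreenError):
    """A field value violates a domain invariant."""


class ConsistencyError(LgtScreenError):
    """Two inputs disagree (e.g. a gene in two orthogroups)."""


class TaxonomyError(LgtScreenError):
    """A taxon label cannot be resolved through the taxonomy map."""

    def __init__(self, labels):
        self.labels = sorted(set(labels))
        super().__init__(
            "unresolvable taxon label(s): " + ", ".join(self.labels)
        )


class ConfigError(LgtScreenError):
    """An infeasible or schema-violating configuration."""
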