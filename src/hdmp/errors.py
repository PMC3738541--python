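"""Exception hierarchy shared across the package."""


class HdmpError(Exception):
    """Base class for all errors raised by hdmp."""


class OntologyIntegrityError(HdmpError):
    """The ontology table violates a structural invariant (duplicate ids,
    dangling tree-number prefixes, empty tables)."""


class UnknownTermError(HdmpError, KeyError):
    """A disease key does not resolve to any ontology term."""

    def __str__(self) -> str:  # KeyError quotes its repr; keep the message plain
        return self.args[0] if self.args else ""


class CoverageError(HdmpError):
    """A lookup table does not cover every item it is asked about."""


class MixedOntologyError(HdmpError):
    """Two disease DAGs built from different ontologies were combined."""


class EmptyInputError(HdmpError):
    """An operation received an empty collection where content is required."""


class EmptyGroupError(HdmpError):
    """A miRNA family/cluster or disease group is empty."""


class ParameterError(HdmpError, ValueError):
    """A numeric parameter is outside its documented range."""


class UnusableMirnaError(HdmpError):
    """A miRNA has no associated diseases left, so its functional
    similarity is undefined."""


class NoLabelsError(HdmpError):
    """A disease has no labeled miRNAs, so candidates cannot be ranked."""


class InsufficientLabelsError(HdmpError):
    """A disease has fewer labeled miRNAs than cross-validation folds."""


class ParseError(HdmpError):
    """A file could not be parsed; carries the path and 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = path
        self.line = line
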