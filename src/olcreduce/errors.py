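"""Exception hierarchy for olcreduce."""


class OlcError(Exception):
    """Base class for all olcreduce errors."""


class ParameterError(OlcError, ValueError):
    """A parameter is outside its documented domain."""


class ParseError(OlcError, ValueError):
    """An input file could not be parsed; the message names the offending record."""


class DuplicateIdError(OlcError, ValueError):
    """Two reads share an identifier."""


class GraphError(OlcError, ValueError):
    """An operation received a graph violating its preconditions."""


class FormatError(OlcError, ValueError):
    """A serialized graph uses an unsupported dialect or is internally inconsistent."""
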