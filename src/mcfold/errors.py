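"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class McfoldError(Exception):
    """Base class for all package errors."""


class ConfigError(McfoldError):
    """Invalid run/analysis configuration (exit code 2)."""


class InputError(McfoldError):
    """Invalid or inconsistent input data (exit code 3)."""


class ParseError(InputError):
    """Malformed structure or topology file; names the offending line."""
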