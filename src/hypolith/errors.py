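"""Exception hierarchy shared across the pipeline."""


class HypolithError(Exception):
    """Base class for all pipeline errors."""


class ParseError(HypolithError):
    """A file could not be parsed (malformed FASTA/FASTQ/TSV record)."""


class ValidationError(HypolithError):
    """Parsed data violates a documented invariant."""


class ConfigError(HypolithError):
    """A configuration value or combination of values is invalid."""
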