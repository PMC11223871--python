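"""Exception hierarchy.

``PgsdeskError`` is the base for every error the package raises on bad
input data or configuration; the CLI maps it to exit code 2.
"""


class PgsdeskError(Exception):
    """Base class for all pgsdesk data/configuration errors."""


class ScoreFileError(PgsdeskError):
    """A scoring file is malformed (e.g. a required column is missing)."""


class EmptyScoreError(ScoreFileError):
    """A scoring file contains no parseable variants."""


class RepositoryError(PgsdeskError):
    """Invalid repository construction or query."""


class VcfError(PgsdeskError):
    """A VCF could not be read (missing index, malformed record, bad DS)."""


class DataError(PgsdeskError):
    """Input values violate their documented domain (e.g. dosage > 2)."""


class ConfigError(PgsdeskError):
    """A parameter is outside its valid range."""
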