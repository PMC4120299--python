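"""Exception hierarchy for qofsmoke."""


class QofSmokeError(Exception):
    """Base class for all qofsmoke errors."""


class RecordValidationError(QofSmokeError, ValueError):
    """One or more indicator records violate the record invariants.

    Carries a list of ``(practice_id, message)`` pairs in :attr:`failures`.
    """

    def __init__(self, failures):
        self.failures = list(failures)
        lines = "; ".join(f"{pid}: {msg}" for pid, msg in self.failures)
        super().__init__(f"{len(self.failures)} invalid record(s): {lines}")


class DuplicateRecordError(QofSmokeError, ValueError):
    """Duplicate (practice, year, indicator) rows in an input table."""


class ConfigError(QofSmokeError, ValueError):
    """Invalid configuration (code map, cohort config, run config)."""


class UndefinedEstimateError(QofSmokeError, ZeroDivisionError):
    """An estimate is undefined (zero denominator or empty group)."""


class InvariantError(QofSmokeError, ValueError):
    """A numeric invariant is violated (e.g. numerator exceeds denominator)."""


class LinkageError(QofSmokeError, KeyError):
    """Postcode-to-district linkage failed for one or more practices.

    :attr:`unmatched` maps practice id to the postcode that had no entry.
    """

    def __init__(self, unmatched):
        self.unmatched = dict(unmatched)
        pairs = ", ".join(f"{pid} ({pc!r})" for pid, pc in sorted(self.unmatched.items()))
        super().__init__(f"no district for {len(self.unmatched)} practice(s): {pairs}")


class InsufficientDataError(QofSmokeError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(QofSmokeError, ValueError):
    """Degenerate input (e.g. constant series where variation is required)."""


class ModelConvergenceError(QofSmokeError, RuntimeError):
    """Maximum-likelihood fit failed to converge; carries the retvals trace."""

    def __init__(self, message, trace=None):
        self.trace = trace
        super().__init__(message)


class CollinearityError(QofSmokeError, ValueError):
    """Design matrix is rank deficient; names the offending covariates."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear or zero-variance covariates: {', '.join(self.columns)}")
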