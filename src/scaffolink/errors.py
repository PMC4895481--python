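"""Exception hierarchy shared across the package."""


class ScaffolinkError(Exception):
    """Base class for all errors raised by scaffolink."""


class DataError(ScaffolinkError):
    """Malformed or inconsistent input data (bad file, missing id, bad value)."""


class CycleError(ScaffolinkError):
    """A precedence graph still contains a cycle where a DAG was required."""


class InconsistentChainsError(CycleError):
    """A cycle consists solely of chain-internal edges: the chains themselves
    impose contradictory order and no map edge can be sacrificed to fix it."""
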