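"""Exception types raised across the pipeline."""


class SchemaError(ValueError):
    """An input table is missing a mandatory column or has a malformed layout."""


class IntegrityError(ValueError):
    """A dataset violates an internal invariant (e.g., duplicate trial rows)."""


class ConfigurationError(ValueError):
    """A configuration value is out of range or inconsistent with the inputs."""


class CueLookupError(KeyError):
    """A requested cue is absent from the registry or a frequency table."""


class DegenerateInputError(ValueError):
    """An input is structurally unusable (empty vocabulary, single factor level...)."""


class UndefinedDistributionError(ValueError):
    """A response distribution cannot be formed (zero tokens in a period)."""


class UndefinedScoreError(ValueError):
    """A summary score has no finite contributions to average."""


class ConvergenceError(RuntimeError):
    """The random-walk expansion does not converge for the given decay."""


class ShortfallError(RuntimeError):
    """Fewer eligible matched pairs exist than permutations requested."""

    def __init__(self, eligible: int, requested: int):
        super().__init__(
            f"only {eligible} eligible matched pairs available, "
            f"{requested} requested"
        )
        self.eligible = eligible
        self.requested = requested
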