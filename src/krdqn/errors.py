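"""Exception hierarchy for the krdqn package."""


class KrdqnError(Exception):
    """Base class for all package-specific errors."""


class GraphParseError(KrdqnError):
    """A graph input file could not be parsed (names file and line number)."""


class GraphValidationError(KrdqnError):
    """A graph violates a structural invariant (e.g. relation/type mismatch)."""


class UnknownNodeError(KrdqnError, KeyError):
    """A node id was looked up that does not exist in the graph."""


class FeatureError(KrdqnError):
    """A node attribute could not be turned into a feature vector."""


class AgentEnvironmentError(KrdqnError):
    """Misuse of the MDP environment (wrong entity type, inadmissible action)."""


class SamplingError(KrdqnError):
    """Negative sampling is impossible for some drug."""


class SplitError(KrdqnError):
    """A drug-level split or fold plan cannot be constructed."""


class UndefinedMetricError(KrdqnError):
    """A classification metric has a zero denominator."""


class TrainingError(KrdqnError):
    """The training task is degenerate (e.g. no demonstration path exists)."""


class GenerationError(KrdqnError):
    """A synthetic-data specification is unsatisfiable."""


class ConfigError(KrdqnError):
    """A pipeline configuration file is missing or malformed."""
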