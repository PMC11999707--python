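"""Exception types shared across the package."""


class InputError(ValueError):
    """Malformed or inconsistent user input (shapes, lengths, ranges)."""


class CapabilityError(RuntimeError):
    """An adapter was asked for a capability it does not offer."""


class ConfigError(ValueError):
    """Invalid configuration value."""


class SizeError(ValueError):
    """A brute-force path was requested beyond its enumeration guard."""


class SolverError(RuntimeError):
    """A linear solve was rank deficient or otherwise ill posed."""


class TrainingError(RuntimeError):
    """An iterative fit diverged (non-finite loss)."""
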