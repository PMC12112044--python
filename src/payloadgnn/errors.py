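"""Exception taxonomy shared across the package.

The CLI maps these onto exit codes (data errors → 3, numeric failures → 4).
"""


class PayloadGNNError(Exception):
    """Base class for package-specific failures."""


class SmilesParseError(PayloadGNNError, ValueError):
    """A SMILES or SMARTS string could not be parsed; carries the string."""

    def __init__(self, text: str, kind: str = "SMILES"):
        self.text = text
        super().__init__(f"unparseable {kind}: {text!r}")


class ShapeError(PayloadGNNError, ValueError):
    """Array dimensions inconsistent with the molecule or configuration."""


class ConfigError(PayloadGNNError, ValueError):
    """Invalid model or training configuration."""


class CapabilityError(PayloadGNNError, RuntimeError):
    """An operation was requested from a model variant that lacks it."""


class NumericError(PayloadGNNError, RuntimeError):
    """Training or evaluation produced non-finite values."""
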