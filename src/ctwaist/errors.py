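"""Exception taxonomy shared across the pipeline.

Pipeline failures are split the way a reading radiologist would triage
them: ``TechnicalFailure`` means the automated landmarking could not
locate the waist (e.g. the bone mask gives no rib/iliac gap), while
``NonEvaluable`` means the scan itself cannot support a circumference
measurement (the body exits the reconstructed field of view, so the skin
contour is clipped).  Both carry a human-readable reason code that ends
up in the measurement report.
"""


class CtwaistError(Exception):
    """Base class for all errors raised by this package."""


class DataError(CtwaistError):
    """Unreadable, missing or inconsistent input data."""


class TechnicalFailure(CtwaistError):
    """Automated waist localization failed (bone landmarks not found)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class NonEvaluable(CtwaistError):
    """Scan cannot be measured: skin mask discontinuous at the image border
    because the body exceeds the reconstructed field of view."""

    def __init__(self, reason: str = "body mask touches the in-plane FOV border"):
        super().__init__(reason)
        self.reason = reason
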