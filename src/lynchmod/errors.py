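"""Exception hierarchy shared across the pipeline stages."""


class PipelineError(Exception):
    """Base class for all pipeline errors; carries the failing stage name."""

    stage: str = "pipeline"


class SchemaError(PipelineError):
    """An input table is missing a mandatory column or violates a uniqueness rule."""

    stage = "input"


class VcfParseError(PipelineError):
    stage = "vcf"


class AnnotationError(PipelineError):
    """A variant cannot be annotated (outside CDS+flank, nonstandard residue, ...)."""

    stage = "annotation"


class IndeterminatePhenotypeError(PipelineError):
    """Subject cannot be classified: unknown EC age and no other tumors."""

    stage = "phenotype"


class LinkageError(PipelineError):
    stage = "linkage"


class DegenerateTableError(PipelineError):
    """A contingency table violates a test precondition (zero margin, empty row)."""

    stage = "association"
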