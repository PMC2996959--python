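"""Shared helpers for pipeline-level tests."""

import hashlib
from pathlib import Path

from srnakit.pipeline import PipelineConfig


def small_pipeline_config(paths: dict, out) -> PipelineConfig:
    refs = {
        name.removeprefix("ref_"): str(p)
        for name, p in paths.items()
        if name.startswith("ref_")
    }
    return PipelineConfig(
        reads=str(paths["reads"]),
        ncrna_refs=refs,
        known=str(paths["known"]),
        transcripts=str(paths["transcripts"]),
        out=str(out),
    )


def hash_outputs(d: Path) -> str:
    """Hash every pipeline output except the provenance copy of the config
    (which embeds absolute paths)."""
    h = hashlib.sha256()
    for p in sorted(Path(d).rglob("*")):
        if p.is_file() and p.name != "config_resolved.yaml":
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
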