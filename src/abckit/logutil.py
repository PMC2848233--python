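"""Run logging: every CLI invocation records its resolved configuration.

The log captures the effective configuration (file values after
command-line overrides) and the RNG seed with a timestamp, so any
stochastic run can be reproduced exactly from its log alone.
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path


def setup_run_log(output_dir, resolved_config_text: str, seed: int,
                  command: str) -> Path:
    """Attach a file handler under ``output_dir`` and write the run preamble."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    log_path = output_dir / "run.log"
    handler = logging.FileHandler(log_path, encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("abckit")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    root.info("command: %s (started %s)", command, stamp)
    root.info("seed: %d", seed)
    for line in resolved_config_text.splitlines():
        root.info("config: %s", line)
    return log_path
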