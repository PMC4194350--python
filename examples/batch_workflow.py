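"""Batch-process plate images into an experiment store, then curate.

Writes three synthetic plate scans to PNG, processes them in batch
(detection -> deposit tables -> summaries, with an audit trail), saves
the experiment directory, flags one deposit as an artefact by editing
the CSV's include column, and re-summarises.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from flyspot import PlateJob, SynthSpec, batch_process, generate_plate, resummarize

workdir = Path(tempfile.mkdtemp(prefix="flyspot_demo_"))
jobs = []
for i in range(3):
    image, _ = generate_plate(SynthSpec(width=300, height=300, n_round=5,
                                        n_oblong=3, seed=60 + i))
    path = workdir / f"plate{i}.png"
    arr = (image.pixels * 255).round().astype(np.uint8)
    Image.fromarray(arr, "RGB").save(path, dpi=(1200, 1200))
    jobs.append(PlateJob(image_path=path, n_flies=6,
                         group="treated" if i else "control"))

store = batch_process(jobs, experiment_id="demo")
store_dir = workdir / "experiment"
store.save(store_dir)
print(f"processed {len(store.plates)} plates, audit entries: {len(store.audit)}")
print(f"store: {sorted(p.name for p in store_dir.iterdir())}")

# curate: mark the largest deposit of plate0 as an artefact
dep_csv = store_dir / "deposits_plate0.csv"
table = pd.read_csv(dep_csv)
table.loc[table["area"].idxmax(), "include"] = 0
table.to_csv(dep_csv, index=False)

before = store.plates["plate0"].summary.all.n_spots
refreshed = resummarize(store_dir)
after = refreshed.plates["plate0"].summary.all.n_spots
print(f"plate0 spots before curation: {before}, after: {after}")

# The include column is the headless equivalent of unticking a deposit
# in an inspector window: summaries always honour the edited flags.
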