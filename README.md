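# managedh5

A data-standardization framework over HDF5:

* **Format specification language** (`managedh5.spec`) — hierarchical,
  JSON-serializable specification documents for files, groups, datasets,
  attributes, dimension scales, managed-type references, and relationship
  attributes; incremental builders, meta-validation, recursive compilation
  (inlining referenced managed types, with cycle detection), and compilation
  of a whole-format document from a type registry.
* **Managed objects** (`managedh5.managed`, `managedh5.registry`) — HDF5
  files/groups/datasets carrying standardized descriptor attributes
  (`MANAGED_TYPE`, `MANAGED_DESCRIPTION`, `MANAGED_SPEC`,
  `MANAGED_OBJECT_ID`); atomic creation that is never left in an invalid
  state, wrap-by-type dispatch, recursive compliance verification with
  minimal-specification semantics (extra objects are always allowed),
  discovery by type (with inheritance), modular storage of managed objects
  in external linked files, and multi-file containers (`entry_#` external
  links).
* **Relationship attributes** (`managedh5.relationships`) — JSON-valued
  `RELATIONSHIP_ATTR_*` attributes declaring typed semantic links between
  objects.  Seven types: `order`, `equivalent`, `indexes`,
  `shared_encoding`, `shared_ascending_encoding`, `indexes_values`, `user`.
  Six of them imply selection-mapping rules (`map_selection`,
  `select_through`); index-map relationships chain two order legs and an
  indexes leg through an explicit integer index map (arbitrary N-to-M,
  `-1` fill sentinels), created and discovered in single calls.
* **Electrophysiology application format** (`managedh5.ephys`) — managed
  types `BrainDataFile` (session hierarchy `/data/{internal,external}`,
  `/descriptors/{static,dynamic}`), `BrainDataCollection`, `BrainDataEphys`
  (2-D space x time voltage array in Volts with electrode-id/time dimension
  scales and stored sampling rate), and `BrainDataEphysProcessed` (3-D
  space x time x band).  Time scales are generated from the sampling rate in
  milliseconds; order relationships between scales and data are created
  automatically; auto-expand mode grows the time axis as blocks are
  appended.
* **Fixtures** (`managedh5.fixtures`) — deterministic synthetic session and
  image-scaling generators plus compliance-violation injection, so the whole
  stack is testable offline.

## CLI

```sh
managedh5 demo session  --out session.h5 --seed 1
managedh5 demo imagemap --out image.h5 --rows 120 --cols 122 --factor 5

managedh5 validate session.h5                 # exit 0 iff compliant
managedh5 inspect session.h5                  # managed objects table
managedh5 inspect session.h5 --relationships  # relationship edge list
managedh5 spec BrainDataEphys --recursive     # JSON format specification

managedh5 map-selection image.h5 --source /source_image \
    --rel image_map --leg MAP_TO_TARGET --sel "36,70"
```

Selection grammar: comma-separated per-axis selectors, each `i` (point),
`a:b` (half-open range), or `[i,j,k]` (index list).  Exit codes: 0 success /
compliant, 1 non-compliant, 2 usage or I/O error.

## Quick example

```python
import numpy as np
import managedh5 as m

session = m.create_session_file("session.h5")
ephys = m.create_ephys(
    session["/data/internal"], "ephys_data_grid",
    raw=np.zeros((4, 100)), sampling_rate=12200.0,
    electrode_ids=np.arange(4),
)
assert m.verify_compliance(ephys).compliant
print(ephys.aux("time")[:3])      # ms, generated from the sampling rate
session.close()
```

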