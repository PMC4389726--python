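# Save a grayscale snapshot of the video stream at every key press.
# Run with:  rivulet run examples/snapshot.yaml --out out
nodes:
- id: cam
  category: source
  operator: fixture
  params: {name: video}
- id: keys
  category: source
  operator: fixture
  params: {name: keys}
- id: snap
  category: combinator
  operator: sample
- id: save
  category: sink
  operator: frame_file
  params: {path: snapshots.frames}
edges:
- [cam, snap, 0]     # slot 0: the data stream
- [keys, snap, 1]    # slot 1: the trigger
- [snap, save, 0]
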