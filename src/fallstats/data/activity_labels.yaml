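# Bundled map from raw activity labels to the five generic movement classes.
# Keys are normalized before lookup: lower-case, hyphens/underscores -> spaces,
# whitespace collapsed.  Any normalized label starting with "fall" resolves to
# the fall class even if it is not listed here (fall subtypes are open-ended).
basic:
  - standing
  - sitting
  - sitting down
  - standing up
  - rising
  - getting up
  - descending
  - lying
  - lying down
  - kneeling
  - bending
  - hand movements
  - making a call
  - applauding
standard:
  - walking
  - going down
  - climbing stairs
  - stairs up
  - stairs down
  - walking upstairs
  - walking downstairs
  - picking
  - picking object
  - picking an object from the floor
  - tying shoelaces
sporting:
  - running
  - jogging
  - jumping
  - hopping
near_fall:
  - near fall
  - stumble
  - trip
  - misstep
fall:
  - fall
  - fall backwards
  - backward fall
  - fall forward
  - forward fall
  - frontal fall
  - fall lateral
  - lateral fall
  - fall slipping
  - slipping
  - fall tripping
  - fall hitting
  - fall bumping
  - fall misstep
  - fall syncope
  - syncope
  - fainting
  - collapse
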