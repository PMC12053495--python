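# Space-group operator table: supported non-centrosymmetric groups.
# Format:  <canonical symbol> | <alias> [| <alias> ...]
# followed by one xyz-triplet symmetry operation per indented line.
# Rhombohedral groups are given in the hexagonal (obverse) setting.

P1 | P 1
  x,y,z

P21 | P 1 21 1 | P 21
  x,y,z
  -x,y+1/2,-z

C2 | C 1 2 1 | C 2
  x,y,z
  -x,y,-z
  x+1/2,y+1/2,z
  -x+1/2,y+1/2,-z

P212121 | P 21 21 21
  x,y,z
  -x+1/2,-y,z+1/2
  x+1/2,-y+1/2,-z
  -x,y+1/2,-z+1/2

P31 | P 31
  x,y,z
  -y,x-y,z+1/3
  -x+y,-x,z+2/3

R3 | R 3 | R 3 :H
  x,y,z
  -y,x-y,z
  -x+y,-x,z
  x+2/3,y+1/3,z+1/3
  -y+2/3,x-y+1/3,z+1/3
  -x+y+2/3,-x+1/3,z+1/3
  x+1/3,y+2/3,z+2/3
  -y+1/3,x-y+2/3,z+2/3
  -x+y+1/3,-x+2/3,z+2/3
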