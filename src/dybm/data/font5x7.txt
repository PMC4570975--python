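; 5x7 block glyphs, one per letter: a name line, then seven rows over {., #}.
; Columns render left-to-right as successive time steps; rows are neurons.

S
.###.
#...#
#....
.###.
....#
#...#
.###.

C
.###.
#...#
#....
#....
#....
#...#
.###.

I
.###.
..#..
..#..
..#..
..#..
..#..
.###.

E
#####
#....
#....
####.
#....
#....
#####

N
#...#
##..#
#.#.#
#..##
#...#
#...#
#...#
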