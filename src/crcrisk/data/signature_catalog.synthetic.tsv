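context	SBS1like	SBS5like	SBS6like	SBS10blike	SBS18like
A[C>A]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.04981090764
A[C>A]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.04981090764
A[C>A]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.04981090764
A[C>A]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.04981090764
C[C>A]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.04981090764
C[C>A]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.04981090764
C[C>A]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.04981090764
C[C>A]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.04981090764
G[C>A]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.1493332006
G[C>A]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.04981090764
G[C>A]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.04981090764
G[C>A]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.1493332006
T[C>A]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.04981090764
T[C>A]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.04981090764
T[C>A]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.04981090764
T[C>A]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	0.04981090764
A[C>G]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
A[C>G]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
A[C>G]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
A[C>G]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
C[C>G]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
C[C>G]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
C[C>G]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
C[C>G]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
G[C>G]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
G[C>G]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
G[C>G]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
G[C>G]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
T[C>G]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
T[C>G]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
T[C>G]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
T[C>G]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
A[C>T]A	0.000244140625	0.015625	0.06173029557	0.001004016064	4.97611465e-05
A[C>T]C	0.000244140625	0.015625	0.06173029557	0.001004016064	4.97611465e-05
A[C>T]G	0.2443847656	0.015625	0.06173029557	0.001004016064	4.97611465e-05
A[C>T]T	0.000244140625	0.015625	0.06173029557	0.001004016064	4.97611465e-05
C[C>T]A	0.000244140625	0.015625	0.06173029557	0.001004016064	4.97611465e-05
C[C>T]C	0.000244140625	0.015625	0.06173029557	0.001004016064	4.97611465e-05
C[C>T]G	0.2443847656	0.015625	0.06173029557	0.001004016064	4.97611465e-05
C[C>T]T	0.000244140625	0.015625	0.06173029557	0.05120481928	4.97611465e-05
G[C>T]A	0.000244140625	0.015625	0.06173029557	0.001004016064	4.97611465e-05
G[C>T]C	0.000244140625	0.015625	0.06173029557	0.001004016064	4.97611465e-05
G[C>T]G	0.2443847656	0.015625	0.06173029557	0.001004016064	4.97611465e-05
G[C>T]T	0.000244140625	0.015625	0.06173029557	0.001004016064	4.97611465e-05
T[C>T]A	0.000244140625	0.015625	0.06173029557	0.001004016064	4.97611465e-05
T[C>T]C	0.000244140625	0.015625	0.06173029557	0.001004016064	4.97611465e-05
T[C>T]G	0.2443847656	0.015625	0.06173029557	0.3022088353	4.97611465e-05
T[C>T]T	0.000244140625	0.015625	0.06173029557	0.5532128514	4.97611465e-05
A[T>A]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
A[T>A]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
A[T>A]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
A[T>A]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
C[T>A]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
C[T>A]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
C[T>A]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
C[T>A]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
G[T>A]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
G[T>A]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
G[T>A]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
G[T>A]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
T[T>A]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
T[T>A]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
T[T>A]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
T[T>A]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
A[T>C]A	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
A[T>C]C	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
A[T>C]G	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
A[T>C]T	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
C[T>C]A	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
C[T>C]C	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
C[T>C]G	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
C[T>C]T	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
G[T>C]A	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
G[T>C]C	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
G[T>C]G	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
G[T>C]T	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
T[T>C]A	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
T[T>C]C	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
T[T>C]G	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
T[T>C]T	0.000244140625	0.015625	0.0001539408867	0.001004016064	4.97611465e-05
A[T>G]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
A[T>G]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
A[T>G]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
A[T>G]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
C[T>G]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
C[T>G]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
C[T>G]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
C[T>G]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
G[T>G]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
G[T>G]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
G[T>G]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
G[T>G]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
T[T>G]A	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
T[T>G]C	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
T[T>G]G	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
T[T>G]T	0.000244140625	0.0078125	0.0001539408867	0.001004016064	4.97611465e-05
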