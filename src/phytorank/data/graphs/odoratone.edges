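# odoratone: hydrogen-suppressed heavy-atom skeleton (C30H48O3)
# single edges regardless of bond order; best-effort reconstruction; molecular formula matches reported monoisotopic mass
C1 C2
C2 C3
C3 C4
C4 C5
C5 O6
C5 C7
C7 C8
C7 C9
C7 O10
C2 C11
C11 C12
C12 C13
C13 C14
C14 C15
C14 C16
C16 C17
C16 C18
C18 C19
C19 C20
C20 C21
C21 C22
C22 C23
C23 O24
C23 C25
C25 C26
C26 C27
C26 C28
C26 C29
C29 C30
C30 C31
C31 C32
C32 C33
C16 C11
C32 C20
C21 C14
C32 C25
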