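# azadirachtin: hydrogen-suppressed heavy-atom skeleton (C35H44O16)
# single edges regardless of bond order; best-effort reconstruction; molecular formula matches reported monoisotopic mass
C1 O2
O2 C3
C3 O4
C3 C5
C5 C6
C6 O7
C6 C8
C8 C9
C9 O10
O10 C11
C11 O12
C11 C13
C13 C14
C13 C15
C15 C16
C9 C17
C17 C18
C17 C19
C19 O20
C19 C21
C21 O22
C21 C23
C23 C24
C24 O25
C24 O26
O26 C27
C23 C28
C28 O29
O29 C30
C30 C31
C30 C32
C32 C33
C33 C34
C34 C35
C35 O36
C34 C37
C37 O38
C37 C39
C39 C40
C40 C41
C41 O42
O42 C43
C43 C44
C43 O45
C41 C46
C46 C47
C39 O48
O48 C49
C49 O50
C49 C51
C51 C5
C49 C6
C46 C17
C46 C23
C39 C28
C37 C32
O36 C34
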