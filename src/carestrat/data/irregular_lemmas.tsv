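sung	sing
sang	sing
sings	sing
went	go
gone	go
goes	go
ran	run
running	run
ate	eat
eaten	eat
gave	give
given	give
took	take
taken	take
made	make
said	say
saw	see
seen	see
told	tell
thought	think
bought	buy
brought	bring
taught	teach
caught	catch
kept	keep
slept	sleep
left	leave
felt	feel
met	meet
sat	sit
stood	stand
woke	wake
wrote	write
written	write
chose	choose
chosen	choose
spoke	speak
spoken	speak
broke	break
broken	break
got	get
found	find
heard	hear
held	hold
knew	know
grew	grow
drew	draw
drawn	draw
children	child
people	person
feet	foot
teeth	tooth
men	man
women	woman
better	good
best	good
worse	bad
worst	bad
perhaps	perhaps
always	always
news	news
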