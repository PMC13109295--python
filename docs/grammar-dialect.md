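# Grammar dialect

UTF-8 text, one statement per line; `#` starts a comment; blank lines are
ignored. Keywords are case-insensitive at the start of a line.

```ebnf
document     = { line } ;
line         = setting | axiom | terminals | sub | rule ;

setting      = ( "angle:" | "step:" ) number ;
axiom        = "axiom:" symbols ;
terminals    = "terminals:" { name } ;          (* optional strict checking *)
sub          = "sub" name "=" path "@" integer [ "iterations" ]
               "class=" ( "leaf" | "branch" ) ;

rule         = predecessor [ ":" expression ] "->" alternatives ;
predecessor  = name [ "(" name { "," name } ")" ] ;
alternatives = branch { "|" branch } ;          (* "|" surrounded by spaces *)
branch       = [ "(" number ")" ] symbols ;     (* leading weight, > 0 *)

symbols      = { symbol } ;
symbol       = ( name | punct ) [ "(" expression { "," expression } ")" ] ;
name         = letter { letter | digit | "_" } ;
punct        = "+" | "-" | "&" | "^" | "\" | "/" | "|" | "["
             | "]" | "{" | "}" | "." | "!" | "'" ;

expression   = arithmetic/boolean over formal parameters:
               + - * /, unary -, parentheses, < <= > >= == !=,
               sin(x), cos(x), pow(x, y)        (* angles in degrees *)
```

Semantics:

- `angle:` / `step:` set the turtle defaults a bare `+` or `F` uses; a
  numeric argument (`+(30)`, `F(0.5)`) overrides them per symbol.
- Rules for the same symbol are tried in file order; the first whose
  condition holds is applied. Successor weights are normalized per rule.
- `sub` binds a placeholder symbol to an organ grammar file (path relative
  to the including file), an iteration count, and an organ class. During
  hierarchical expansion each placeholder occurrence becomes a freshly
  derived organ string wrapped in span markers with a new instance id.
- With a `terminals:` line present, any identifier that is neither a rule
  predecessor, a declared terminal, nor a bound placeholder is an
  undeclared-symbol error; without it, unknown identifiers are implicit
  terminals (the turtle ignores ones it has no command for).
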